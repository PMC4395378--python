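"""Locate the fitness-cliff discontinuities in conductance space.

Bisects the conduction-failure boundaries at 26 degC (the highest water
temperature the squid encounters, where conduction is most fragile).
Expect ~81 mS/cm^2 for the sodium threshold and a potassium window of
roughly [4, 88] mS/cm^2: outside these, the axon is functionally silent
and a fitness cliff appears.
"""

from chanevo import find_threshold

na_min = find_threshold("na", fixed_value=36.0, predicate="conducts", bracket=(40, 160))
print(f"minimum conducting G_Na at G_K=36, 26 degC : {na_min:.0f} mS/cm^2")

k_lo = find_threshold("k", fixed_value=120.0, predicate="conducts", bracket=(1, 20))
k_hi = find_threshold("k", fixed_value=120.0, predicate="conducts", bracket=(60, 120))
print(f"conducting G_K window at G_Na=120, 26 degC : [{k_lo:.0f}, {k_hi:.0f}] mS/cm^2")
print("below the window the axon fails to repolarize; above it the wave dies")
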