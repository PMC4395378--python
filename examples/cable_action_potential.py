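"""Simulate one propagating action potential and read out its physiology.

Builds the squid giant-axon cable at the experimentally observed
conductances (G_Na = 120, G_K = 36 mS/cm^2, 18.5 degC), applies the brief
20 uA stimulus to the first compartment and prints the standard metrics.
"""

from chanevo import CableParams, Conductances, analyze_trace, simulate

params = CableParams()  # 10 cm cable, printed defaults, 18.5 degC
cond = Conductances.fitted(120.0, 36.0, params)
print(f"fitted leak reversal V_L = {cond.v_l:.2f} mV (rest stationary at -65 mV)")

trace = simulate(params, cond)
metrics = analyze_trace(trace)

print(f"conducted to the distal site : {metrics.conducted}")
print(f"conduction velocity          : {metrics.velocity_m_per_s:.2f} m/s")
print(f"Na charge per AP (mid-axon)  : {metrics.na_flux_nc_per_cm2:.0f} nC/cm^2")
print(f"APD50 / APD90                : {metrics.apd50_ms:.3f} / {metrics.apd90_ms:.3f} ms")

# The velocity is the speed of the fully developed wave between 2.5 and
# 7.5 cm; the flux is the metabolic price of one spike, which selection
# could in principle act on.
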