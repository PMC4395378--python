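"""Evolve sodium-channel expression against a conduction fitness cliff.

A diploid population of 2000 individuals starts at the observed G_Na of
120 mS/cm^2 (mean allele 12, step 5). Biased mutation (90% of mutations
weaken the promoter/CRM) erodes expression; a step fitness cliff at
81 mS/cm^2 (conduction failure at 26 degC) removes the weakest phenotypes.
With binomial phenotypic noise (SD 13.2 mS/cm^2) the balance settles near
the observed value; without noise it slides down against the cliff.

Desk scale: 3000 generations, N = 2000 (the full study scale is N = 5000,
10000 generations).
"""

import numpy as np

from chanevo import EvolutionConfig, LocusConfig, cliff, run_evolution

for noise_n, label in ((0, "no phenotypic noise"), (28, "noise SD 13.2 mS/cm^2")):
    cfg = EvolutionConfig(
        loci=(LocusConfig("g_na", allele_step=5.0, init_mean_allele=12, noise_n=noise_n),),
        fitness=cliff(81.0),
        n_individuals=2000,
        generations=3000,
        seed=42,
    )
    traj = run_evolution(cfg)
    final = traj.equilibrium_mean(500)[0]
    sd = traj.sd[-1, 0]
    print(f"{label:26s}: final mean G_Na = {final:6.1f} +- {sd:4.1f} mS/cm^2")

print("the noise-free population piles up just above the cliff (~92);")
print("phenotypic noise forces a safety margin and holds the mean near 120")
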