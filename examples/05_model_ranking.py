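"""AIC ranking of demographic-model fits and diffusion-unit scaling.

Uses the three published two-population fits (isolation-with-migration,
strict isolation, ancient symmetric migration).  AIC = 2k − 2·LL; the
IM model wins.  Scaling then converts diffusion units to natural units:
N_anc = θ/(4μL), sizes ν·N_anc, times 2·N_anc·T generations, migration
m/(2·N_anc) per generation.
"""

import divergescan as ds

fits = [
    ds.ModelFit("isolation_migration", -1193.96, 7,
                {"theta": 8683.75, "s": 0.335, "nu1": 4.313, "nu2": 10.068,
                 "m12": 0.0017, "m21": 0.0005, "T": 0.1041,
                 "misid": 0.043}),
    ds.ModelFit("strict_isolation", -1225.36, 4,
                {"theta": 8750.87, "nu1": 3.167, "nu2": 14.333,
                 "T": 0.0692, "misid": 0.043}),
    ds.ModelFit("ancient_symmetric_migration", -1225.2, 6,
                {"theta": 8756.92, "nu1": 3.372, "nu2": 9.838, "m": 0.00004,
                 "T1": 0.011, "T2": 0.0587, "misid": 0.043}),
]

print(ds.rank_models(fits).to_string(index=False))

# μ·L chosen so θ anchors N_anc near 2,990 diploids, generation time 2 y
ctx = ds.ScalingContext(mutation_rate=1e-8, generation_time=2.0,
                        sequence_length=8683.75 / (4e-8 * 2990.17))
natural = ds.scale_to_natural_units(fits[0], ctx)
for name, value in natural.items():
    print(f"{name:20s} {value:,.4f}")
# T_years is the divergence time in years; m12_per_generation the
# fraction of population 2 replaced by migrants from population 1 each
# generation.
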