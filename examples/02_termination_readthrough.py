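"""Quantify terminator read-through from a single-round transcription gel.

Builds a single-terminator construct (13-nt initiation region halting at
the first C, terminated product at the six-U terminator, 170-nt full
length), simulates triplicate gel lanes across a Na+ titration with an ON
switch dose response, and converts band volumes to molar fractions with
the radiolabel correction factor.
"""

from riboquant import (
    LabelingScheme,
    NoiseModel,
    SwitchParams,
    random_construct,
    readthrough_prob,
    readthrough_series,
    simulate_transcription,
)
from riboquant.synthetic import effective_na_mM

construct = random_construct(seed=7, init_len=13, elong_len=157, u_run=6)
species = construct.species()
labeling = LabelingScheme.preset("single-2022")  # 7% / 0.2% labelled UTP

t, fl = species
print(f"construct {construct.name}: halt at {construct.halt_index}, "
      f"T ends at {t.end}, FL at {fl.end}")
print(f"U counts   T: init {t.u_init} / elong {t.u_elong}   "
      f"FL: init {fl.u_init} / elong {fl.u_elong}")

switch = SwitchParams("ON", k_half=2.2, p_floor=0.02, p_ceil=0.8,
                      ligand="Na+", unit="mM")
lanes = []
for nominal in (0.0, 1.0, 3.0, 10.0, 30.0, 100.0):
    p = readthrough_prob(effective_na_mM(nominal), switch)
    for rep in range(3):
        lane, _ = simulate_transcription(
            species, (p,), n_molecules=20_000, labeling=labeling,
            noise=NoiseModel(cv=0.10, seed=int(nominal * 10) * 100 + rep),
            condition=f"{nominal:05.1f} mM Na+", lane_id=f"{nominal:g}-r{rep}",
        )
        lanes.append(lane)

per_lane, per_condition = readthrough_series(lanes, species, labeling)
print("\nfraction FL per condition (mean of 3 replicate lanes):")
for _, row in per_condition.iterrows():
    print(f"  {row['condition']:>12}: {row['fraction_FL']:.3f}")
print()
print("Rising Na+ suppresses terminator formation, so the full-length")
print("fraction climbs toward the 80% read-through ceiling. Note the")
print("zero-supplement lane is already half-activated: the transcription")
print("buffer itself contributes ~4 mM Na+, about twice this switch's")
print("2.2 mM midpoint.")
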