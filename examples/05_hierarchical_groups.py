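"""Rescue overlapping species with a human-judged grouping character.

When two species' wing outlines overlap, no outline-only classifier can
fully separate them.  If a second character (judged by eye, e.g. a compound
eye feature) splits the species into groups, one independent model per group
removes all cross-group confusion by construction.  This example compares
flat vs grouped validation on the same data and seed.
"""

from wingid.classify import run_repeated_validation
from wingid.config import RunConfig
from wingid.pipeline import specimens_to_table
from wingid.synthetic import default_family_specs, generate_family

specs = default_family_specs(n_specimens=16, seed=0)
specimens = [s for spec in specs for s in generate_family(spec)]
table = specimens_to_table(specimens, n_harmonics=30)
cfg = RunConfig(ga_population=10, ga_generations=10)

flat = run_repeated_validation(table, config=cfg, seed=1)
# put the overlapping pair (notched / notched_ii) into different groups
group_of = {"broad": "group1", "notched": "group1",
            "slender": "group2", "notched_ii": "group2"}
grouped = run_repeated_validation(table, config=cfg, seed=1, group_of=group_of)

pair_flat = (flat.misid_matrix.loc["notched", "notched_ii"]
             + flat.misid_matrix.loc["notched_ii", "notched"])
pair_grouped = (grouped.misid_matrix.loc["notched", "notched_ii"]
                + grouped.misid_matrix.loc["notched_ii", "notched"])

print(f"flat model:     mean test accuracy {flat.mean_test:6.2f}%, "
      f"notched<->notched_ii confusion {pair_flat:5.2f}%")
print(f"grouped models: mean test accuracy {grouped.mean_test:6.2f}%, "
      f"notched<->notched_ii confusion {pair_grouped:5.2f}%")
print()
print("Grouping drives the cross-group misidentification to exactly zero -")
print("those species never meet inside one classifier - and overall accuracy")
print("rises accordingly.")
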