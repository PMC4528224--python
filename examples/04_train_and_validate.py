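"""Train and validate a species classifier on synthetic outline families.

Generates the default four families (two of them deliberately overlapping),
runs repeated randomized 1:1 train/test validation with a GA-tuned RBF-SVM,
and prints the per-run, per-species and misidentification summaries.
A reduced GA budget keeps the example quick; drop the overrides for the
full defaults.
"""

from wingid.classify import pca_overlap, run_repeated_validation
from wingid.config import RunConfig
from wingid.pipeline import specimens_to_table
from wingid.synthetic import default_family_specs, generate_family

specs = default_family_specs(n_specimens=16, seed=0)
specimens = [s for spec in specs for s in generate_family(spec)]
table = specimens_to_table(specimens, n_harmonics=30)

cfg = RunConfig(ga_population=10, ga_generations=10)
report = run_repeated_validation(table, config=cfg, seed=1)

print("run   CV%     test%")
for _, row in report.runs.iterrows():
    print(f"{int(row['run']):3d}  {row['cv_accuracy']:6.2f}  {row['test_accuracy']:6.2f}")
print(f"mean {report.mean_cv:6.2f}  {report.mean_test:6.2f}")

print("\nper-species identification accuracy (pooled over runs):")
for species, acc in report.per_species_accuracy.items():
    print(f"  {species:12s} {acc:6.2f}%")

print("\nnon-zero misidentification rates P_e (A identified as B):")
m = report.misid_matrix
for a in m.index:
    for b in m.columns:
        if a != b and m.loc[a, b] > 0:
            print(f"  {a:12s} -> {b:12s} {m.loc[a, b]:6.2f}%")

emb = pca_overlap(table)
print(f"\nPC1+PC2 carry {100 * emb.explained_fraction:.1f}% of descriptor variance;")
print("the confused pair (notched / notched_ii) overlaps in that plane, the")
print("well-separated families do not - misidentification concentrates there.")
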