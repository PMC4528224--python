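"""Generate synthetic wing-outline families and render them as an image tree.

Builds the four default families (two well-separated, two deliberately
overlapping), renders every specimen as a dark silhouette on white, and
writes the layout the training command consumes, plus a ground-truth CSV of
each specimen's exact normalized descriptors.
"""

from pathlib import Path

from wingid.synthetic import default_family_specs, write_image_tree

out = Path("scratch_examples/families")
specs = default_family_specs(n_specimens=6, seed=0)
truth = write_image_tree(specs, out, canvas_px=256)

print(f"wrote {len(truth)} specimens into {out}/<family>/<specimen>.png")
print(truth.groupby("label")["applied_scale"].agg(["count", "mean"]).round(3))
print()
print("Each row of ground_truth.csv holds the exact normalized elliptic")
print("Fourier features of that specimen's generating curve - the values the")
print("image pipeline is expected to recover up to rasterization error.")
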