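"""One specimen through the whole digitization chain, stage by stage.

Renders a noise-free wing-like silhouette, extracts its binary outline,
chain-codes it, computes elliptic Fourier coefficients and normalizes them,
then compares the result with the exact descriptors of the generating curve.
"""

import numpy as np

from wingid.chaincode import to_coordinates, trace
from wingid.efd import compute_efd, normalize
from wingid.outline import binarize, clean_and_fill, extract_outline, to_grayscale
from wingid.synthetic import (
    ShapeFamilySpec,
    generate_family,
    ground_truth_efd,
    render_to_image,
    shipped_prototypes,
)

spec = ShapeFamilySpec("falcate", shipped_prototypes()["falcate"],
                       coeff_noise_sd=0.0, rotation_range=0.0,
                       scale_range=(1, 1), n_specimens=1, seed=0)
specimen = generate_family(spec)[0]
image = render_to_image(specimen, canvas_px=512)

gray = to_grayscale(image)
cleaned = clean_and_fill(binarize(gray))
outline = extract_outline(cleaned)
chain = trace(outline)
coords = to_coordinates(chain)
efd = normalize(compute_efd(coords, n_harmonics=10))
truth = ground_truth_efd(specimen, n_harmonics=10)

print(f"outline pixels:     {len(outline)}")
print(f"chain perimeter T:  {chain.total_T:.1f} px "
      f"({int(np.sum(chain.codes % 2 == 0))} axis steps, "
      f"{int(np.sum(chain.codes % 2 == 1))} diagonal steps)")
print(f"normalized first harmonic: {np.round(efd.coeffs[0], 6)}")
print(f"max |recovered - exact| over 10 harmonics: "
      f"{np.abs(efd.coeffs - truth.coeffs).max():.4f}")
print()
print("The first harmonic is (1, 0, 0, d1) by construction of the")
print("normalization; d1 is the axis ratio of the best-fitting ellipse, and")
print("the residual error (~0.005) is pure rasterization noise at 512 px.")
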