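"""End-to-end plumbing: image (or coordinates) -> normalized feature vector.

One call per specimen runs the whole chain: read -> grayscale -> binarize ->
clean/fill -> outline -> chain code -> elliptic Fourier -> normalize ->
flatten.  Directory helpers build labelled feature tables from the
``<dir>/<species>/<image>`` layout used for training.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import chaincode, efd, outline
from .errors import WingidError

logger = logging.getLogger(__name__)

IMAGE_SUFFIXES = (".bmp", ".png", ".jpg", ".jpeg")


def image_to_stages(image) -> dict:
    """Run the extraction chain on an image (path or array); return all stages.

    Keys: ``gray``, ``binary``, ``cleaned``, ``outline`` (BinaryOutline),
    ``chain`` (ChainCode), ``coords`` ((t, x, y) rows).
    """
    img = outline.read_image(image) if isinstance(image, (str, Path)) else np.asarray(image)
    gray = outline.to_grayscale(img)
    binary = outline.binarize(gray)
    cleaned = outline.clean_and_fill(binary)
    ol = outline.extract_outline(cleaned)
    cc = chaincode.trace(ol)
    coords = chaincode.to_coordinates(cc)
    return {"gray": gray, "binary": binary, "cleaned": cleaned,
            "outline": ol, "chain": cc, "coords": coords}


def image_to_efd(image, n_harmonics: int) -> efd.EFDSet:
    """Normalized elliptic Fourier descriptors of one image."""
    coords = image_to_stages(image)["coords"]
    return efd.normalize(efd.compute_efd(coords, n_harmonics))


def image_to_features(image, n_harmonics: int, label=None, source=None) -> efd.FeatureVector:
    """Normalized feature vector (length 4N - 3) of one image."""
    return efd.to_feature_vector(image_to_efd(image, n_harmonics), label=label, source=source)


def folder_to_table(train_dir, n_harmonics: int, on_error: str = "skip"):
    """Build a labelled feature table from ``<train_dir>/<species>/<image>``.

    Returns ``(table, skipped)`` where ``skipped`` lists (path, reason) for
    unreadable/unprocessable images (``on_error='skip'``, logged as
    warnings); with ``on_error='raise'`` the first failure propagates.
    """
    train_dir = Path(train_dir)
    if not train_dir.is_dir():
        raise WingidError(f"{train_dir} is not a directory")
    class_dirs = sorted(p for p in train_dir.iterdir() if p.is_dir())
    rows, skipped = [], []
    names = efd.feature_names(n_harmonics)
    for class_dir in class_dirs:
        images = sorted(p for p in class_dir.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES)
        for path in images:
            try:
                fv = image_to_features(path, n_harmonics)
            except Exception as exc:
                if on_error == "raise":
                    raise
                logger.warning("skipping %s: %s", path, exc)
                skipped.append((str(path), str(exc)))
                continue
            row = {"source": str(path), "label": class_dir.name}
            row.update(dict(zip(names, fv.values)))
            rows.append(row)
    table = pd.DataFrame(rows, columns=["source", "label", *names])
    return table, skipped


def specimens_to_table(specimens, n_harmonics: int) -> pd.DataFrame:
    """Feature table from synthetic specimens' exact coordinates (no raster)."""
    rows = []
    names = efd.feature_names(n_harmonics)
    counter: dict = {}
    for sp in specimens:
        i = counter.get(sp.family_id, 0)
        counter[sp.family_id] = i + 1
        fv = efd.to_feature_vector(efd.normalize(efd.compute_efd(sp.points, n_harmonics)))
        row = {"source": f"{sp.family_id}:{i:03d}", "label": sp.family_id}
        row.update(dict(zip(names, fv.values)))
        rows.append(row)
    return pd.DataFrame(rows, columns=["source", "label", *names])
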