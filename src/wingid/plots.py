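"""Diagnostic figure writers (backend-free: matplotlib Figure objects only)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
from matplotlib.figure import Figure
from PIL import Image


def save_stage_images(stages: dict, out_dir) -> list:
    """Write the processing-chain stages (gray, binary, cleaned, outline) as PNGs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    ol = stages["outline"]
    outline_img = np.full(ol.image_shape, 255, dtype=np.uint8)
    outline_img[ol.pixels[:, 0], ol.pixels[:, 1]] = 0
    named = [
        ("stage1_gray.png", stages["gray"]),
        ("stage2_binary.png", np.where(stages["binary"], 0, 255).astype(np.uint8)),
        ("stage3_cleaned.png", np.where(stages["cleaned"], 0, 255).astype(np.uint8)),
        ("stage4_outline.png", outline_img),
    ]
    for name, img in named:
        path = out / name
        Image.fromarray(img).save(path)
        paths.append(path)
    return paths


def plot_ce_variation(diag, path) -> None:
    """CE per harmonic (bars) and cumulative-CE variation (line)."""
    fig = Figure(figsize=(7, 4))
    ax = fig.add_subplot(111)
    harmonics = np.arange(1, len(diag.ce) + 1)
    ax.bar(harmonics, diag.ce, color="0.7", label="CE per harmonic")
    ax2 = ax.twinx()
    ax2.plot(harmonics[1:], diag.ce_variation, "o-", color="C3", ms=3, label="CE variation")
    ax.set_xlabel("harmonic content number")
    ax.set_ylabel("CE")
    ax2.set_ylabel("variation of cumulative CE")
    fig.tight_layout()
    fig.savefig(path, dpi=120)


def plot_epsilon(ns, eps, path) -> None:
    """Reconstruction error epsilon_n versus harmonic count."""
    fig = Figure(figsize=(6, 4))
    ax = fig.add_subplot(111)
    ax.plot(ns, eps, "o-", ms=3)
    ax.set_xlabel("harmonic content number n")
    ax.set_ylabel("reconstruction error $\\epsilon_n$ (px)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)


def plot_reconstruction_overlay(coords, recon, n_use, path) -> None:
    """Original outline against its n-harmonic reconstruction."""
    fig = Figure(figsize=(5, 5))
    ax = fig.add_subplot(111)
    ax.plot(coords[:, 1], coords[:, 2], "-", color="0.6", lw=1, label="original")
    closed = np.vstack([recon, recon[:1]])
    ax.plot(closed[:, 0], closed[:, 1], "-", color="C3", lw=1, label=f"n = {n_use}")
    ax.set_aspect("equal")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
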