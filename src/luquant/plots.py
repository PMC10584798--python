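"""Characterization figures: noise/resolution versus updates, recovery
curves, and phantom cross-sections with their ideal rectangular
profiles."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .quality import extract_profile  # noqa: E402

__all__ = ["plot_noise_resolution", "plot_rc_curves", "plot_cylinder_profiles"]

_ALG_COLORS = {"OSEM": "tab:blue", "BSREM": "tab:orange"}


def _alg_label(row) -> str:
    if row.algorithm == "BSREM" and row.beta > 0:
        return f"BSREM-RDP (beta={row.beta:g})"
    return row.algorithm


def plot_noise_resolution(quality_df, resolution_df=None, path=None):
    """Noise (and optionally matched-filter FWHM) versus updates."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for (alg, beta), sub in quality_df[quality_df.subsets == 1].groupby(
        ["algorithm", "beta"]
    ):
        sub = sub.sort_values("updates")
        ax.plot(sub.updates, sub.cv, "o-",
                label=_alg_label(sub.iloc[0]), alpha=0.8)
    ax.set_xscale("log")
    ax.set_xlabel("updates (iterations x subsets)")
    ax.set_ylabel("noise CV in VOI_inside", color="tab:blue")
    ax.legend(fontsize=8)
    if resolution_df is not None and len(resolution_df):
        ax2 = ax.twinx()
        cold = resolution_df[
            (resolution_df.background == "cold") & (resolution_df.subsets == 1)
        ]
        for (alg, beta), sub in cold.groupby(["algorithm", "beta"]):
            sub = sub.sort_values("updates")
            ax2.plot(sub.updates, sub.fwhm_mm, "s--", color="tab:red", alpha=0.6)
        ax2.set_ylabel("matched-filter FWHM [mm]", color="tab:red")
    fig.tight_layout()
    if path:
        fig.savefig(Path(path), dpi=120)
        plt.close(fig)
    return fig


def plot_rc_curves(rc_df, path=None):
    """Recovery coefficient versus sphere diameter per protocol."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for (alg, upd, beta, bg), sub in rc_df.groupby(
        ["algorithm", "updates", "beta", "background"]
    ):
        sub = sub.sort_values("sphere_mm")
        ls = "-" if bg == "cold" else ":"
        ax.plot(sub.sphere_mm, sub.rc_percent, ls, marker="o", alpha=0.7,
                color=_ALG_COLORS.get(alg, "k"),
                label=f"{_alg_label(sub.iloc[0])} {upd}u ({bg})")
    ax.set_xlabel("sphere diameter [mm]")
    ax.set_ylabel("recovery coefficient [%]")
    ax.set_ylim(0, 110)
    ax.axhline(100, color="k", lw=0.5)
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path:
        fig.savefig(Path(path), dpi=120)
        plt.close(fig)
    return fig


def plot_cylinder_profiles(volumes, truth_counts_per_voxel, diameter_mm,
                           path=None):
    """Cross-sections through the cylinder centre for a set of
    reconstructions, with the ideal rectangular profile overlaid."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for params, vol in volumes.items():
        coords, vals = extract_profile(vol, 0, (0.0, 0.0, 0.0))
        ax.plot(coords, vals, alpha=0.7, label=params.label)
    coords, _ = extract_profile(next(iter(volumes.values())), 0, (0, 0, 0))
    ideal = (abs(coords) <= diameter_mm / 2) * truth_counts_per_voxel
    ax.plot(coords, ideal, "k-", lw=1.2, label="ideal")
    ax.set_xlabel("x [mm]")
    ax.set_ylabel("counts per voxel")
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path:
        fig.savefig(Path(path), dpi=120)
        plt.close(fig)
    return fig
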