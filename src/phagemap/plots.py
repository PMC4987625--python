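"""Optional matplotlib views of library complexity and enrichment profiles."""

from __future__ import annotations

import numpy as np

from .enrichment import LibraryCounts, ResidueEnrichmentProfile
from .hotspots import HotspotCall


def _plt():
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    return plt


def plot_library_complexity(counts: LibraryCounts, path: str) -> None:
    """Unique fragments versus copy number (library diversity view)."""
    plt = _plt()
    copies = np.array(list(counts.fragment_counts.values()))
    values, n_unique = np.unique(copies, return_counts=True)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(values, n_unique, s=12)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("copies per unique fragment")
    ax.set_ylabel("number of unique fragments")
    ax.set_title(counts.library_id)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_occurrence(profile: ResidueEnrichmentProfile, path: str) -> None:
    """Per-residue occurrence before and after selection."""
    plt = _plt()
    x = np.arange(1, len(profile) + 1)
    fig, axes = plt.subplots(2, 1, sharex=True, figsize=(8, 5))
    axes[0].fill_between(x, profile.occurrence_unselected, color="0.4")
    axes[0].set_ylabel("occurrence (unselected)")
    axes[1].fill_between(x, profile.occurrence_selected, color="0.1")
    axes[1].set_ylabel("occurrence (selected)")
    axes[1].set_xlabel("residue (fusion coordinates)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_enrichment_profile(
    profile: ResidueEnrichmentProfile,
    path: str,
    hotspot_calls: list[HotspotCall] | None = None,
    contact_points_fusion: list[int] | None = None,
) -> None:
    """Enrichment factor along the protein with called jump boundaries."""
    plt = _plt()
    x = np.arange(1, len(profile) + 1)
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.plot(x, profile.enrichment_factor, lw=1.0, color="0.1")
    ax.set_yscale("log")
    ax.set_xlabel("residue (fusion coordinates)")
    ax.set_ylabel("enrichment factor")
    for call in hotspot_calls or []:
        color = "red" if call.direction == "increase" else "blue"
        ax.axvline(call.boundary, color=color, ls="--", lw=0.8)
    if contact_points_fusion:
        ax.plot(contact_points_fusion,
                np.full(len(contact_points_fusion),
                        profile.enrichment_factor.min()),
                "r.", ms=4)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
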