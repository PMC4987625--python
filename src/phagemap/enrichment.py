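"""Per-residue occurrence, enrichment factor and enriched-fragment calls.

Given the natural-frame fragments of an unselected and an affinity-selected
library, this module computes

* per-residue occurrence: the read-weighted fraction of a library's
  natural-frame reads whose fragment covers each residue;
* the per-residue enrichment factor

      EF[i] = ((Csel[i] + pc) / Nsel) / ((Cunsel[i] + pc) / Nunsel)

  where C are raw per-residue read tallies, N the libraries' natural-frame
  read totals and pc a pseudocount (default 1) that keeps EF finite and
  positive everywhere;
* fragment frequency rankings and the mean + 5 SD significance rule: a
  fragment is significantly enriched when its frequency in the selected
  library exceeds the mean plus five standard deviations of the frequency
  distribution over unique fragments of the unselected library.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .antigen import ReferenceAntigen, ResidueSpan

UNSELECTED = "unselected"
SELECTED = "selected"


@dataclass
class LibraryCounts:
    """Read counts per unique fragment (residue span) for one library.

    Fragments from different nucleotide placements that encode the same
    residue span are collapsed; counts are read-weighted, so
    ``sum(fragment_counts.values()) == total_natural_reads``.
    """

    library_id: str
    fragment_counts: dict[ResidueSpan, int]
    total_natural_reads: int

    def __post_init__(self) -> None:
        total = sum(self.fragment_counts.values())
        if total != self.total_natural_reads:
            raise ValueError(
                f"count conservation violated: fragments sum to {total}, "
                f"total_natural_reads is {self.total_natural_reads}"
            )
        if any(c < 1 for c in self.fragment_counts.values()):
            raise ValueError("fragment counts must be >= 1")

    @classmethod
    def from_fragments(cls, fragments, library_id: str = UNSELECTED) -> "LibraryCounts":
        """Collapse classified reads to unique natural-frame residue spans."""
        counts = Counter(
            f.span_res for f in fragments
            if f.frame_class == "natural" and f.span_res is not None
        )
        return cls(library_id=library_id, fragment_counts=dict(counts),
                   total_natural_reads=sum(counts.values()))

    @classmethod
    def from_spans(cls, spans, counts, library_id: str) -> "LibraryCounts":
        """Build directly from parallel span/count sequences (counts >= 1)."""
        mapping: Counter = Counter()
        for span, c in zip(spans, counts):
            if c > 0:
                mapping[span] += int(c)
        return cls(library_id=library_id, fragment_counts=dict(mapping),
                   total_natural_reads=int(sum(mapping.values())))


@dataclass
class ResidueEnrichmentProfile:
    """Per-residue occurrence and enrichment-factor vectors (length = protein).

    Raw per-residue read tallies and library totals are kept so downstream
    change-point detection can standardize jump scores by their counting
    uncertainty.
    """

    occurrence_unselected: np.ndarray
    occurrence_selected: np.ndarray
    enrichment_factor: np.ndarray
    pseudocount: float = 1.0
    counts_unselected: np.ndarray | None = None
    counts_selected: np.ndarray | None = None
    n_unselected: int | None = None
    n_selected: int | None = None

    def __len__(self) -> int:
        return len(self.enrichment_factor)


@dataclass
class EnrichedFragmentCall:
    """A unique selected-library fragment with its frequencies and call."""

    span: ResidueSpan
    frequency_selected: float
    frequency_unselected: float | None = None
    significant: bool | None = None


def _coverage_counts(counts: LibraryCounts, n_residues: int) -> np.ndarray:
    """Read-weighted per-residue coverage tally via a difference array."""
    delta = np.zeros(n_residues + 1, dtype=float)
    for span, c in counts.fragment_counts.items():
        delta[span.start_res - 1] += c
        delta[span.end_res] -= c
    return np.cumsum(delta[:-1])


def residue_occurrence(counts: LibraryCounts, ref: ReferenceAntigen) -> np.ndarray:
    """Per-residue occurrence normalized by the library's natural-read total."""
    if counts.total_natural_reads <= 0:
        raise ValueError("occurrence undefined: library has zero natural-frame reads")
    return _coverage_counts(counts, ref.n_residues) / counts.total_natural_reads


def enrichment_factor(
    sel: LibraryCounts,
    unsel: LibraryCounts,
    ref: ReferenceAntigen,
    pseudocount: float = 1.0,
    depth_normalize: bool = True,
) -> ResidueEnrichmentProfile:
    """Pseudocount-stabilized per-residue selected/unselected enrichment.

    With ``depth_normalize`` (default) the tallies are divided by each
    library's natural-read total so EF is comparable across sequencing
    depths; ``depth_normalize=False`` gives the raw-count ratio
    ``(Csel + pc) / (Cunsel + pc)``.
    """
    if not sel.fragment_counts or not unsel.fragment_counts:
        raise ValueError("both libraries must contain at least one fragment")
    L = ref.n_residues
    c_sel = _coverage_counts(sel, L)
    c_unsel = _coverage_counts(unsel, L)
    if depth_normalize:
        ef = ((c_sel + pseudocount) / sel.total_natural_reads) / (
            (c_unsel + pseudocount) / unsel.total_natural_reads
        )
    else:
        ef = (c_sel + pseudocount) / (c_unsel + pseudocount)
    return ResidueEnrichmentProfile(
        occurrence_unselected=c_unsel / unsel.total_natural_reads,
        occurrence_selected=c_sel / sel.total_natural_reads,
        enrichment_factor=ef,
        pseudocount=pseudocount,
        counts_unselected=c_unsel,
        counts_selected=c_sel,
        n_unselected=unsel.total_natural_reads,
        n_selected=sel.total_natural_reads,
    )


def _frequencies(counts: LibraryCounts) -> dict[ResidueSpan, float]:
    n = counts.total_natural_reads
    return {span: c / n for span, c in counts.fragment_counts.items()}


def significance_threshold(unsel: LibraryCounts) -> float:
    """Mean + 5 sample SD of unique-fragment frequencies in the unselected library."""
    freqs = np.array(list(_frequencies(unsel).values()))
    if len(freqs) < 2:
        raise ValueError(
            "significance threshold undefined: the unselected library needs "
            ">= 2 unique fragments (use a larger / more diverse library)"
        )
    return float(freqs.mean() + 5.0 * freqs.std(ddof=1))


def rank_fragments(
    sel: LibraryCounts,
    top_n: int = 30,
    unsel: LibraryCounts | None = None,
) -> list[EnrichedFragmentCall]:
    """Unique selected fragments ranked by frequency (descending).

    Ties are broken by longer span first, then by smaller start residue.
    When ``unsel`` is given, unselected frequencies and the mean + 5 SD
    significance flag are filled in.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    sel_freq = _frequencies(sel)
    unsel_freq = _frequencies(unsel) if unsel is not None else {}
    threshold = significance_threshold(unsel) if unsel is not None else None
    ranked = sorted(
        sel_freq.items(),
        key=lambda kv: (-kv[1], -len(kv[0]), kv[0].start_res),
    )
    if top_n < len(ranked):
        ranked = ranked[:top_n]
    calls = []
    for span, f in ranked:
        calls.append(EnrichedFragmentCall(
            span=span,
            frequency_selected=f,
            frequency_unselected=unsel_freq.get(span, 0.0) if unsel else None,
            significant=(f > threshold) if threshold is not None else None,
        ))
    return calls


def call_significant(
    sel: LibraryCounts, unsel: LibraryCounts
) -> list[EnrichedFragmentCall]:
    """Apply the mean + 5 SD rule to every unique selected fragment.

    Returns calls for all unique selected fragments (frequency-ranked) with
    the ``significant`` flag set; filter on the flag for the significant set.
    """
    return rank_fragments(sel, top_n=len(sel.fragment_counts), unsel=unsel)
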