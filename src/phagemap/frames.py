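"""Insert extraction, mapping and reading-frame classification.

A clone displays its insert only when the random cloning lottery is won on
all three counts: forward orientation (1/2), in-frame 5' junction (1/3) and
insert length divisible by three so the downstream capsid fusion stays in
frame (1/3).  Exactly 1 of the 18 (orientation x frame5 x len_mod3)
configurations is therefore "natural frame", and a random fragment library
is expected to contain ~1/18 = 5.6% natural-frame clones.  Clones that win
the lottery but carry a stop codon in the displayed frame cannot display
peptide and are classed non-natural.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import edlib
import numpy as np
from Bio.Seq import Seq, reverse_complement

from .antigen import FUSION, ReferenceAntigen, ResidueSpan

logger = logging.getLogger(__name__)

# frame classes
NATURAL = "natural"
NON_NATURAL = "non_natural"
EMPTY = "empty"
UNMAPPED = "unmapped"

FORWARD = "forward"
REVERSE = "reverse"


class EmptySetError(ValueError):
    """Raised when a statistic is requested for an empty fragment set."""


@dataclass
class InsertRead:
    """A read reduced to its insert (vector flanks removed)."""

    read_id: str
    insert_seq: str
    source_library: str = "unselected"


@dataclass
class MappedFragment:
    """An insert located on the reference CDS with its frame bookkeeping.

    ``frame5`` is the 5' junction offset relative to the vector fusion frame
    (0 means the insert starts on a codon boundary of the reference CDS);
    ``span_res`` holds the residues whose codons lie entirely inside
    ``span_nt``.  Span fields are ``None`` for empty or unmapped reads.
    """

    read_id: str
    frame_class: str
    orientation: str | None = None
    span_nt: tuple[int, int] | None = None
    span_res: ResidueSpan | None = None
    frame5: int | None = None
    len_mod3: int | None = None
    edit_distance: int | None = None


@dataclass
class ClassificationSummary:
    """Read-level tallies for one classified library."""

    n_total: int = 0
    n_empty: int = 0
    n_natural: int = 0
    n_non_natural: int = 0
    n_unmapped: int = 0

    @property
    def fraction_natural(self) -> float | None:
        """Natural-frame fraction among insert-bearing, mappable reads.

        The denominator excludes empty (wild-type) and unmapped reads; with
        no such reads the fraction is undefined and reported as ``None``.
        """
        denom = self.n_natural + self.n_non_natural
        if denom == 0:
            return None
        return self.n_natural / denom

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_empty": self.n_empty,
            "n_natural": self.n_natural,
            "n_non_natural": self.n_non_natural,
            "n_unmapped": self.n_unmapped,
            "fraction_natural": self.fraction_natural,
        }


def _hamming_find(seq: str, pattern: str, max_mismatch: int) -> tuple[int, int] | None:
    """Leftmost best Hamming match of ``pattern`` in ``seq``.

    Returns ``(position, mismatches)`` or ``None`` if no window is within
    ``max_mismatch``.  Ties on the mismatch count are broken by the leftmost
    occurrence (logged).
    """
    n, m = len(seq), len(pattern)
    if m == 0 or m > n:
        return None
    pos = seq.find(pattern)
    if pos >= 0:
        return pos, 0
    if max_mismatch <= 0:
        return None
    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    p = np.frombuffer(pattern.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(a, m)
    mm = (windows != p).sum(axis=1)
    best = int(mm.min())
    if best > max_mismatch:
        return None
    if int((mm == best).sum()) > 1:
        logger.debug("flank matched %d windows with %d mismatches; keeping leftmost",
                     int((mm == best).sum()), best)
    return int(np.argmin(mm)), best


def extract_insert(
    raw_read: str,
    vector_flanks: tuple[str, str],
    max_mismatch: int = 2,
    read_id: str = "",
    source_library: str = "unselected",
) -> InsertRead | None:
    """Cut the insert out of a read between the two vector flank sequences.

    Returns ``None`` when either flank cannot be located within
    ``max_mismatch`` substitutions (the read is then counted unmapped).  An
    empty insert (flanks directly adjacent) is a wild-type / empty-vector
    clone and is returned with ``insert_seq == ""``.
    """
    flank_l, flank_r = vector_flanks
    if not flank_l or not flank_r:
        raise ValueError("both vector flank sequences must be non-empty")
    raw_read = raw_read.upper()
    hit_l = _hamming_find(raw_read, flank_l, max_mismatch)
    if hit_l is None:
        return None
    insert_start = hit_l[0] + len(flank_l)
    hit_r = _hamming_find(raw_read[insert_start:], flank_r, max_mismatch)
    if hit_r is None:
        return None
    insert = raw_read[insert_start:insert_start + hit_r[0]]
    return InsertRead(read_id=read_id, insert_seq=insert, source_library=source_library)


def _span_res_from_nt(start_nt: int, end_nt: int) -> ResidueSpan | None:
    """Residues whose codons are entirely inside the 1-based nt span."""
    # smallest r with 3r-2 >= start_nt; largest r with 3r <= end_nt
    first = -(-(start_nt + 2) // 3)
    last = end_nt // 3
    if first > last:
        return None
    return ResidueSpan(first, last, FUSION)


def map_insert(
    insert: InsertRead,
    ref: ReferenceAntigen,
    min_match_len: int = 15,
    max_mismatch_frac: float = 0.02,
) -> MappedFragment:
    """Locate an insert on the reference CDS and classify its frame.

    Exact substring search is tried first (forward, then reverse
    complement); failing that, a banded edit-distance alignment (edlib,
    infix mode) with tolerance ``max_mismatch_frac * len(insert)`` is used.
    Multiple equally good placements keep the leftmost and are logged.
    """
    seq = insert.insert_seq.upper()
    if len(seq) == 0:
        return MappedFragment(read_id=insert.read_id, frame_class=EMPTY)
    if len(seq) < min_match_len:
        return MappedFragment(read_id=insert.read_id, frame_class=UNMAPPED)

    cds = ref.cds
    placement = None  # (start0, end0, orientation, distance)
    pos = cds.find(seq)
    if pos >= 0:
        placement = (pos, pos + len(seq) - 1, FORWARD, 0)
    else:
        rc = reverse_complement(seq)
        pos = cds.find(rc)
        if pos >= 0:
            placement = (pos, pos + len(seq) - 1, REVERSE, 0)
    if placement is None:
        k = int(max_mismatch_frac * len(seq))
        best = None
        for orient, query in ((FORWARD, seq), (REVERSE, reverse_complement(seq))):
            res = edlib.align(query, cds, mode="HW", task="locations", k=k)
            d = res["editDistance"]
            if d < 0:
                continue
            loc = min(res["locations"])  # leftmost placement
            if len(res["locations"]) > 1:
                logger.debug("read %s: %d equally good placements, keeping leftmost",
                             insert.read_id, len(res["locations"]))
            if best is None or d < best[3]:
                best = (loc[0], loc[1], orient, d)
        placement = best
    if placement is None:
        return MappedFragment(read_id=insert.read_id, frame_class=UNMAPPED)

    start0, end0, orientation, dist = placement
    start_nt, end_nt = start0 + 1, end0 + 1
    frame5 = (start_nt - 1) % 3
    len_mod3 = len(seq) % 3
    span_res = _span_res_from_nt(start_nt, end_nt)

    frame_class = NON_NATURAL
    if orientation == FORWARD and frame5 == 0 and len_mod3 == 0:
        displayed = str(Seq(seq).translate())
        frame_class = NON_NATURAL if "*" in displayed else NATURAL

    return MappedFragment(
        read_id=insert.read_id,
        frame_class=frame_class,
        orientation=orientation,
        span_nt=(start_nt, end_nt),
        span_res=span_res,
        frame5=frame5,
        len_mod3=len_mod3,
        edit_distance=dist,
    )


def merge_pairs(
    read1: str,
    read2: str,
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.1,
) -> str:
    """Merge a read pair by 3' overlap; fall back to read 1 if unmergeable.

    ``read2`` is reverse-complemented and the longest overlap with at most
    ``max_mismatch_frac`` mismatching positions wins.
    """
    r2 = reverse_complement(read2.upper())
    r1 = read1.upper()
    max_ov = min(len(r1), len(r2))
    for ov in range(max_ov, min_overlap - 1, -1):
        a, b = r1[-ov:], r2[:ov]
        mm = sum(1 for x, y in zip(a, b) if x != y)
        if mm <= max_mismatch_frac * ov:
            return r1 + r2[ov:]
    logger.debug("unmergeable pair; using read 1 only")
    return r1


def classify_library(
    reads,
    ref: ReferenceAntigen,
    vector_flanks: tuple[str, str] | None = None,
    max_mismatch: int = 2,
    min_match_len: int = 15,
    max_mismatch_frac: float = 0.02,
    source_library: str = "unselected",
) -> tuple[list[MappedFragment], ClassificationSummary]:
    """Classify every read of a library as empty/natural/non-natural/unmapped.

    ``reads`` is an iterable of ``(read_id, sequence)`` pairs.  When
    ``vector_flanks`` is given the insert is first excised from each raw
    read; otherwise reads are taken to be pre-trimmed inserts.  The summary
    is invariant under permutations of the read stream.
    """
    fragments: list[MappedFragment] = []
    summary = ClassificationSummary()
    for read_id, seq in reads:
        summary.n_total += 1
        if vector_flanks is not None:
            insert = extract_insert(
                seq, vector_flanks, max_mismatch=max_mismatch,
                read_id=read_id, source_library=source_library,
            )
            if insert is None:
                fragments.append(MappedFragment(read_id=read_id, frame_class=UNMAPPED))
                summary.n_unmapped += 1
                continue
        else:
            insert = InsertRead(read_id=read_id, insert_seq=seq,
                                source_library=source_library)
        frag = map_insert(insert, ref, min_match_len=min_match_len,
                          max_mismatch_frac=max_mismatch_frac)
        fragments.append(frag)
        if frag.frame_class == EMPTY:
            summary.n_empty += 1
        elif frag.frame_class == NATURAL:
            summary.n_natural += 1
        elif frag.frame_class == NON_NATURAL:
            summary.n_non_natural += 1
        else:
            summary.n_unmapped += 1
    return fragments, summary


def fragment_length_stats(
    fragments: list[MappedFragment],
) -> tuple[float, float, float]:
    """(mean, median, sample sd) of natural-frame fragment lengths, in aa."""
    lengths = [len(f.span_res) for f in fragments
               if f.frame_class == NATURAL and f.span_res is not None]
    if not lengths:
        raise EmptySetError("no natural-frame fragments: length statistics undefined")
    mean = float(np.mean(lengths))
    median = float(np.median(lengths))
    sd = float(np.std(lengths, ddof=1)) if len(lengths) > 1 else 0.0
    return mean, median, sd
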