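"""Synthetic biopanning: fragment libraries and affinity selection with truth.

The generator emulates the construction of a gene-fragment display library
and its affinity selection:

* the reference CDS is randomly fragmented: fragment length uniform on a
  configured bp range (default 100-400 bp, the gel cut used for such
  libraries; an alternative truncated-normal mode emulates the shorter
  55 +/- 18 aa distribution observed for displayed fragments), start
  uniform over the positions where the fragment fits;
* each clone inserts its fragment in a random orientation; a configurable
  fraction of clones is "empty" (wild-type vector, no insert);
* reads are the insert between two fixed vector flanks with uniform
  substitution errors (default rate 0.001) and constant base quality;
* selection draws ``reads_per_round`` clones per round from a multinomial
  whose weights favour binders; round r+1 resamples round r's output.

A clone is a binder (ground truth) when it is natural frame and its residue
span covers every residue of every planted required set.  The default
weight model is strictly conjunctive; ``partial_credit=True`` instead gives
each covered set a multiplicative boost of (w_binder/w_background)^(1/n_sets),
so clones covering a subset of the required stretches are intermediately
enriched (as observed for fragments carrying only the contact stretch of a
two-stretch epitope).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import reverse_complement

from .antigen import ANTIGEN_LOCAL, FUSION, ReferenceAntigen, ResidueSpan, convert_span
from .frames import _span_res_from_nt

# Arbitrary synthetic vector flank sequences (not taken from any real vector).
DEFAULT_FLANK_LEFT = "TGCAGGTCGACTCTAGAGGA"
DEFAULT_FLANK_RIGHT = "CCTAGGACGTCGTACGTACG"

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def synthetic_reference(
    n_residues: int = 438,
    numbering_offset: int = 183,
    seed: int = 0,
    name: str = "synthetic-fusion-antigen",
    contact_points: list[int] | None = None,
) -> ReferenceAntigen:
    """A random stop-free CDS standing in for a real fusion-antigen gene.

    Defaults mirror the shape of a 1314 bp carrier--antigen fusion CDS
    (438 residues) whose antigen moiety starts at fusion residue
    ``numbering_offset + 1``.
    """
    rng = np.random.default_rng(seed)
    codons = []
    for i in range(n_residues):
        if i == 0:
            codons.append("ATG")
            continue
        while True:
            codon = "".join(rng.choice(list("ACGT"), size=3))
            if codon not in _STOPS:
                break
        codons.append(codon)
    return ReferenceAntigen(
        name=name,
        cds="".join(codons),
        numbering_offset=numbering_offset,
        contact_points=contact_points,
    )


@dataclass
class SimConfig:
    """Study conditions for one simulated library + selection."""

    ref: ReferenceAntigen
    n_clones: int = 2000
    empty_fraction: float = 0.1
    fragment_length_range: tuple[int, int] = (100, 400)
    length_distribution: str = "uniform"  # or "normal" (truncated)
    length_mean_bp: float = 165.0  # ~55 aa, used by the "normal" mode
    length_sd_bp: float = 54.0  # ~18 aa
    epitope_required_sets: list[ResidueSpan] = field(default_factory=list)
    w_binder: float = 100.0
    w_background: float = 1.0
    partial_credit: bool = False
    n_rounds: int = 2
    reads_per_round: int = 5000
    seq_error_rate: float = 0.001
    flanks: tuple[str, str] = (DEFAULT_FLANK_LEFT, DEFAULT_FLANK_RIGHT)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.empty_fraction <= 1.0):
            raise ValueError("empty_fraction must be in [0, 1]")
        if not (0.0 <= self.seq_error_rate <= 1.0):
            raise ValueError("seq_error_rate must be in [0, 1]")
        lo, hi = self.fragment_length_range
        if lo < 3 or lo > hi:
            raise ValueError("fragment_length_range must satisfy 3 <= min <= max")
        if hi > self.ref.n_nt:
            raise ValueError(
                f"fragment_length_range max {hi} exceeds gene length {self.ref.n_nt}"
            )
        if not (self.w_binder >= self.w_background > 0):
            raise ValueError("need w_binder >= w_background > 0")

    def required_sets_fusion(self) -> list[ResidueSpan]:
        return [
            convert_span(s, FUSION, self.ref) if s.coordinate_system == ANTIGEN_LOCAL
            else s
            for s in self.epitope_required_sets
        ]


@dataclass
class CloneRecord:
    """Ground truth for one clone of the simulated library."""

    clone_id: int
    is_empty: bool
    insert_seq: str = ""  # as cloned (already reverse-complemented if reverse)
    span_nt: tuple[int, int] | None = None
    orientation: str | None = None
    frame5: int | None = None
    len_mod3: int | None = None
    is_natural: bool = False
    span_res: ResidueSpan | None = None
    is_binder: bool = False


@dataclass
class SimTruth:
    """Per-clone truth plus the planted epitope model."""

    clones: list[CloneRecord]
    epitope_sets_fusion: list[ResidueSpan]
    expected_natural_fraction: float = 1.0 / 18.0

    @property
    def n_binders(self) -> int:
        return sum(c.is_binder for c in self.clones)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Uniform substitution errors at ``rate`` per base."""
    if rate <= 0 or not seq:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    positions = rng.choice(len(seq), size=n_err, replace=False)
    arr = bytearray(seq.encode())
    for p in positions:
        current = arr[p]
        choices = [b for b in _BASES if b != current]
        arr[p] = int(rng.choice(choices))
    return arr.decode()


def _clone_read(clone: CloneRecord, cfg: SimConfig, rng: np.random.Generator) -> str:
    flank_l, flank_r = cfg.flanks
    return _mutate(flank_l + clone.insert_seq + flank_r, cfg.seq_error_rate, rng)


def _draw_lengths(cfg: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    lo, hi = cfg.fragment_length_range
    if cfg.length_distribution == "uniform":
        return rng.integers(lo, hi + 1, size=n)
    if cfg.length_distribution == "normal":
        lengths = rng.normal(cfg.length_mean_bp, cfg.length_sd_bp, size=n)
        return np.clip(np.rint(lengths), lo, hi).astype(int)
    raise ValueError(f"unknown length_distribution {cfg.length_distribution!r}")


def simulate_library(cfg: SimConfig) -> tuple[list[tuple[str, str]], SimTruth]:
    """One QC read per clone of a freshly constructed library, plus truth.

    Returns ``(reads, truth)`` where reads are ``(read_id, sequence)``
    pairs.  Fixed seed implies byte-identical output.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    cds = cfg.ref.cds
    L = cfg.ref.n_nt
    required = cfg.required_sets_fusion()

    empties = rng.random(cfg.n_clones) < cfg.empty_fraction
    lengths = _draw_lengths(cfg, cfg.n_clones, rng)
    # start uniform over the positions where the fragment fits in the gene
    starts = (rng.random(cfg.n_clones) * (L - lengths + 1)).astype(int) + 1
    reverse = rng.random(cfg.n_clones) < 0.5

    clones: list[CloneRecord] = []
    for i in range(cfg.n_clones):
        if empties[i]:
            clones.append(CloneRecord(clone_id=i, is_empty=True))
            continue
        s, ln = int(starts[i]), int(lengths[i])
        e = s + ln - 1
        fragment = cds[s - 1:e]
        orient = "reverse" if reverse[i] else "forward"
        insert = reverse_complement(fragment) if reverse[i] else fragment
        frame5 = (s - 1) % 3
        len_mod3 = ln % 3
        natural = orient == "forward" and frame5 == 0 and len_mod3 == 0
        span_res = _span_res_from_nt(s, e)
        binder = bool(
            natural
            and required
            and span_res is not None
            and all(span_res.contains(req) for req in required)
        )
        clones.append(CloneRecord(
            clone_id=i, is_empty=False, insert_seq=insert, span_nt=(s, e),
            orientation=orient, frame5=frame5, len_mod3=len_mod3,
            is_natural=natural, span_res=span_res, is_binder=binder,
        ))

    reads = [(f"clone_{c.clone_id}", _clone_read(c, cfg, rng)) for c in clones]
    truth = SimTruth(clones=clones, epitope_sets_fusion=required)
    return reads, truth


def clone_weights(truth: SimTruth, cfg: SimConfig) -> np.ndarray:
    """Selection weight per clone under the configured binding model."""
    n_sets = len(truth.epitope_sets_fusion)
    w = np.full(len(truth.clones), cfg.w_background, dtype=float)
    if n_sets == 0:
        return w
    if cfg.partial_credit:
        boost = (cfg.w_binder / cfg.w_background) ** (1.0 / n_sets)
        for i, c in enumerate(truth.clones):
            if not c.is_natural or c.span_res is None:
                continue
            covered = sum(c.span_res.contains(req)
                          for req in truth.epitope_sets_fusion)
            w[i] = cfg.w_background * boost ** covered
    else:
        for i, c in enumerate(truth.clones):
            if c.is_binder:
                w[i] = cfg.w_binder
    return w


def simulate_selection(
    truth: SimTruth, cfg: SimConfig, rounds: int | None = None
) -> tuple[list[tuple[str, str]], list[np.ndarray]]:
    """Multinomial affinity selection over ``n_rounds`` rounds.

    Each round draws ``reads_per_round`` clones with probability
    proportional to (current abundance) x (binding weight); the next round
    resamples the previous round's output.  Returns the final-round reads
    (with fresh sequencing errors) and the per-round clone-count vectors
    (each summing to ``reads_per_round``).
    """
    n_rounds = cfg.n_rounds if rounds is None else rounds
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    rng = np.random.default_rng([cfg.seed, 1])
    w = clone_weights(truth, cfg)
    if w.sum() == 0:
        raise ValueError("no clone has positive selection weight")
    abundance = np.ones(len(truth.clones), dtype=float)
    round_counts: list[np.ndarray] = []
    for _ in range(n_rounds):
        p = abundance * w
        p = p / p.sum()
        counts = rng.multinomial(cfg.reads_per_round, p)
        round_counts.append(counts)
        abundance = counts.astype(float)

    reads: list[tuple[str, str]] = []
    final = round_counts[-1]
    for i in np.flatnonzero(final):
        clone = truth.clones[i]
        for j in range(int(final[i])):
            reads.append((f"sel_{clone.clone_id}_{j}", _clone_read(clone, cfg, rng)))
    return reads, round_counts


def resample_library(
    truth: SimTruth, cfg: SimConfig, n_reads: int, stream: int = 2
) -> tuple[list[tuple[str, str]], np.ndarray]:
    """A plain (selection-free) sequencing sample of the clone pool.

    Useful as the unselected-library read set when sequencing depth exceeds
    clone diversity, and as a null "selection" (equal weights).
    """
    rng = np.random.default_rng([cfg.seed, stream])
    n = len(truth.clones)
    counts = rng.multinomial(n_reads, np.full(n, 1.0 / n))
    reads: list[tuple[str, str]] = []
    for i in np.flatnonzero(counts):
        clone = truth.clones[i]
        for j in range(int(counts[i])):
            reads.append((f"resample{stream}_{clone.clone_id}_{j}",
                          _clone_read(clone, cfg, rng)))
    return reads, counts


def write_fastq(reads: list[tuple[str, str]], path: str, quality: str = "I") -> None:
    """Write ``(read_id, seq)`` pairs as FASTQ with constant base quality."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{quality * len(seq)}\n")


def write_truth_tsv(truth: SimTruth, path: str) -> None:
    """Tab-separated per-clone ground truth."""
    cols = ("clone_id", "is_empty", "orientation", "nt_start", "nt_end",
            "frame5", "len_mod3", "is_natural", "res_start", "res_end", "is_binder")
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for c in truth.clones:
            row = [
                c.clone_id, int(c.is_empty), c.orientation or ".",
                c.span_nt[0] if c.span_nt else ".",
                c.span_nt[1] if c.span_nt else ".",
                c.frame5 if c.frame5 is not None else ".",
                c.len_mod3 if c.len_mod3 is not None else ".",
                int(c.is_natural),
                c.span_res.start_res if c.span_res else ".",
                c.span_res.end_res if c.span_res else ".",
                int(c.is_binder),
            ]
            fh.write("\t".join(str(x) for x in row) + "\n")
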