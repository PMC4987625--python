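"""Change-point ("hot spot") detection on per-residue enrichment profiles.

Abrupt increases of the enrichment factor along the antigen sequence mark
the start of residue stretches required for antibody binding; the boundary
between residues i-1 and i is scored either by the raw difference
EF[i] - EF[i-1] or by the log ratio log(EF[i] / EF[i-1]) (default, since EF
is a ratio quantity).  Boundaries are called where the absolute score is an
outlier under a robust median + k * MAD rule.

When the profile carries raw count tallies, log-ratio scores are first
standardized by a delta-method standard error: the sampling variance of a
jump score scales with the inverse local coverage, so raw scores are
heteroscedastic and a global MAD threshold calibrated on deeply covered
mid-protein residues would fire on noise at the sparsely covered termini.
Standardized calls additionally require |z| above an absolute floor
(default 4).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import median_abs_deviation

from .antigen import FUSION, ResidueSpan
from .enrichment import ResidueEnrichmentProfile

logger = logging.getLogger(__name__)

INCREASE = "increase"
DECREASE = "decrease"

DIFFERENCE = "difference"
LOG_RATIO = "log_ratio"


@dataclass
class HotspotCall:
    """A called boundary: the jump occurs between residues boundary-1 and boundary."""

    boundary: int
    direction: str
    jump_score: float
    passes_threshold: bool = True


def _ef_vector(profile) -> np.ndarray:
    if isinstance(profile, ResidueEnrichmentProfile):
        return np.asarray(profile.enrichment_factor, dtype=float)
    return np.asarray(profile, dtype=float)


def jump_scores(profile, mode: str = LOG_RATIO) -> np.ndarray:
    """Scores for the L-1 inter-residue boundaries of an EF profile.

    ``scores[j]`` belongs to the boundary between residues j+1 and j+2
    (1-based), i.e. to boundary residue j+2.  The pseudocount guarantees
    EF > 0, so the log ratio is always defined.
    """
    ef = _ef_vector(profile)
    if len(ef) < 2:
        raise ValueError("EF vector must have length >= 2")
    if mode == DIFFERENCE:
        return np.diff(ef)
    if mode == LOG_RATIO:
        return np.diff(np.log(ef))
    raise ValueError(f"unknown jump-score mode {mode!r}")


def _jump_standard_errors(profile: ResidueEnrichmentProfile) -> np.ndarray:
    """Delta-method SE of each log-ratio jump score from the count tallies.

    Treats the four tallies entering a jump as independent Poisson counts;
    adjacent tallies actually share most reads, so this overestimates the
    mid-profile variance and is conservative.
    """
    pc = profile.pseudocount
    var_sel = 1.0 / (np.asarray(profile.counts_selected, dtype=float) + pc)
    var_unsel = 1.0 / (np.asarray(profile.counts_unselected, dtype=float) + pc)
    var_log_ef = var_sel + var_unsel
    return np.sqrt(var_log_ef[1:] + var_log_ef[:-1])


def _mad_threshold(abs_scores: np.ndarray, k_mad: float) -> float:
    med = float(np.median(abs_scores))
    mad = float(median_abs_deviation(abs_scores, scale=1.0))
    if mad == 0.0 and np.ptp(abs_scores) > 0:
        logger.warning("MAD of jump scores is 0 on a non-constant profile; "
                       "falling back to the standard deviation")
        mad = float(abs_scores.std())
    return med + k_mad * mad


def call_hotspots(
    profile,
    k_mad: float = 7.0,
    min_separation: int = 5,
    mode: str = LOG_RATIO,
    standardize: bool = True,
    z_min: float = 4.0,
) -> list[HotspotCall]:
    """Call boundaries whose jump score is a robust outlier.

    A boundary is called where |score| > median(|score|) + k_mad * MAD(|score|);
    calls closer than ``min_separation`` residues keep only the larger
    score.  On count-bearing profiles (and ``mode="log_ratio"``) scores are
    SE-standardized and must also exceed ``z_min``.
    """
    if k_mad <= 0:
        raise ValueError("k_mad must be > 0")
    scores = jump_scores(profile, mode=mode)
    standardized = (
        standardize
        and mode == LOG_RATIO
        and isinstance(profile, ResidueEnrichmentProfile)
        and profile.counts_selected is not None
        and profile.counts_unselected is not None
    )
    if standardized:
        scores = scores / _jump_standard_errors(profile)
    abs_scores = np.abs(scores)
    if np.ptp(abs_scores) == 0:
        return []
    threshold = _mad_threshold(abs_scores, k_mad)
    if standardized:
        threshold = max(threshold, z_min)
    idx = np.flatnonzero(abs_scores > threshold)
    calls = [
        HotspotCall(
            boundary=int(j) + 2,  # scores[j] sits between residues j+1 and j+2
            direction=INCREASE if scores[j] > 0 else DECREASE,
            jump_score=float(scores[j]),
        )
        for j in idx
    ]
    # greedy merge: keep the locally largest |score| among calls closer than
    # min_separation
    calls.sort(key=lambda c: -abs(c.jump_score))
    kept: list[HotspotCall] = []
    for call in calls:
        if all(abs(call.boundary - k.boundary) >= min_separation for k in kept):
            kept.append(call)
    kept.sort(key=lambda c: c.boundary)
    return kept


def candidate_required_region(
    call: HotspotCall, profile
) -> ResidueSpan:
    """Maximal run on the high-EF side of a boundary staying above the pre-jump level.

    For an increase at boundary b the run extends rightwards from b while EF
    stays above EF[b-1]; for a decrease it extends leftwards from b-1 while
    EF stays above EF[b].  The returned span is a candidate binding-required
    stretch in fusion coordinates.
    """
    if not call.passes_threshold:
        raise ValueError("candidate region is defined only for passing calls")
    ef = _ef_vector(profile)
    L = len(ef)
    b = call.boundary
    if call.direction == INCREASE:
        level = ef[b - 2]  # EF at residue b-1
        end = b
        while end < L and ef[end] > level:  # ef[end] is residue end+1
            end += 1
        return ResidueSpan(b, end, FUSION)
    level = ef[b - 1]  # EF at residue b
    start = b - 1
    while start > 1 and ef[start - 2] > level:  # ef[start-2] is residue start-1
        start -= 1
    return ResidueSpan(start, b - 1, FUSION)
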