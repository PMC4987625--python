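"""Solution-phase K_D from competition ELISA via the Friguet/Klotz plot.

In the competition format a fixed antibody concentration i0 is equilibrated
with a dilution series of soluble antigen a0; the absorbance A of each
mixture on an antigen-coated plate is proportional to free antibody, and A0
is the absorbance without competitor.  Under antigen excess (a0 >> i0) the
free-antigen concentration is ~a0 and

    A0 / (A0 - A) = 1 + K_D / a0,

so ordinary least squares of y = A0/(A0-A) on x = 1/a0 has slope K_D and
intercept 1.  An exact-quadratic fit (no excess approximation) is provided
as a cross-check.  Concentrations are handled in nM throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

#: plate-coating concentrations (nM) used for the four replicate estimates
DEFAULT_COATING_NM = (3.5, 7.0, 14.0, 28.0)
#: seven-point competitor dilution series spanning 7-480 nM
DEFAULT_A0_GRID_NM = (7.5, 15.0, 30.0, 60.0, 120.0, 240.0, 480.0)
DEFAULT_ANTIBODY_NM = 0.7


@dataclass
class ElisaSeries:
    """One competition-ELISA dilution series (one coating replicate)."""

    antigen_id: str
    points: list[tuple[float, float]]  # (a0 in nM, absorbance A)
    a0_absorbance: float  # A0: absorbance without competing antigen
    coating_conc: float | None = None  # nM
    antibody_conc: float = DEFAULT_ANTIBODY_NM  # nM

    def __post_init__(self) -> None:
        if self.a0_absorbance <= 0:
            raise ValueError("A0 must be positive")
        if any(a0 <= 0 for a0, _ in self.points):
            raise ValueError("competitor concentrations a0 must be positive")


@dataclass
class KdFit:
    """Result of a single-series Friguet fit."""

    antigen_id: str
    kd: float | None  # nM; None when no binding is measurable
    intercept: float | None = None
    n_points_used: int = 0
    no_binding: bool = False
    warnings: list[str] = field(default_factory=list)


@dataclass
class KdEstimate:
    """Replicate-aggregated K_D with fold change versus a reference antigen."""

    antigen_id: str
    kd_values: list[float]
    kd_mean: float | None
    kd_sd: float | None
    fold_change_vs_reference: float | None = None
    no_binding_flag: bool = False


def friguet_kd(series: ElisaSeries, intercept_tol: float = 0.2) -> KdFit:
    """Fit K_D (nM) from one series by the linearized competition plot.

    Non-inhibiting points (A >= A0) are dropped with a warning; a series
    with no informative point at all is reported as "no binding" rather
    than an error, mirroring antigens for which no interaction is
    detectable.  Warns when the antigen-excess assumption (a0 >= 10 i0) or
    the intercept-near-1 diagnostic is violated.
    """
    fit = KdFit(antigen_id=series.antigen_id, kd=None)
    informative = [(a0, A) for a0, A in series.points if A < series.a0_absorbance]
    dropped = len(series.points) - len(informative)
    if dropped:
        msg = f"dropped {dropped} non-inhibiting point(s) with A >= A0"
        fit.warnings.append(msg)
        logger.warning("%s: %s", series.antigen_id, msg)
    if len(informative) == 0:
        fit.no_binding = True
        return fit
    if len(informative) < 2:
        raise ValueError(
            f"{series.antigen_id}: need >= 2 informative points for the "
            f"regression, got {len(informative)}"
        )
    a0 = np.array([p[0] for p in informative])
    A = np.array([p[1] for p in informative])
    if np.any(a0 < 10.0 * series.antibody_conc):
        fit.warnings.append(
            "some a0 < 10 x antibody concentration: antigen-excess "
            "approximation may bias K_D"
        )
    x = 1.0 / a0
    y = series.a0_absorbance / (series.a0_absorbance - A)
    res = stats.linregress(x, y)
    fit.kd = float(res.slope)
    fit.intercept = float(res.intercept)
    fit.n_points_used = len(informative)
    if abs(fit.intercept - 1.0) > intercept_tol:
        msg = (f"intercept {fit.intercept:.3f} deviates from 1 by more than "
               f"{intercept_tol}: check A0 or the excess assumption")
        fit.warnings.append(msg)
        logger.warning("%s: %s", series.antigen_id, msg)
    return fit


def exact_quadratic_kd(series: ElisaSeries) -> KdFit:
    """Cross-check fit solving the exact 1:1 binding quadratic.

    Free antibody fraction at equilibrium with total antigen a0, total
    antibody i0 and constant K_D:

        bound = ((a0 + i0 + K_D) - sqrt((a0 + i0 + K_D)^2 - 4 a0 i0)) / 2
        A / A0 = 1 - bound / i0

    K_D is found by least squares on the absorbances; no antigen-excess
    approximation is involved.
    """
    informative = [(a0, A) for a0, A in series.points if A < series.a0_absorbance]
    if len(informative) < 2:
        fit = KdFit(antigen_id=series.antigen_id, kd=None, no_binding=True)
        return fit
    a0 = np.array([p[0] for p in informative])
    A = np.array([p[1] for p in informative])
    i0 = series.antibody_conc
    A0 = series.a0_absorbance

    def residuals(log_kd):
        kd = np.exp(log_kd[0])
        s = a0 + i0 + kd
        bound = (s - np.sqrt(s * s - 4.0 * a0 * i0)) / 2.0
        return A0 * (1.0 - bound / i0) - A

    sol = optimize.least_squares(residuals, x0=[np.log(np.median(a0))])
    return KdFit(antigen_id=series.antigen_id, kd=float(np.exp(sol.x[0])),
                 intercept=None, n_points_used=len(informative))


def aggregate_kd(
    replicates: list[ElisaSeries],
    reference: KdEstimate | None = None,
) -> KdEstimate:
    """Mean and sample SD of per-replicate K_D values, plus fold change.

    Replicates are the series measured at the different plate-coating
    concentrations.  If every replicate shows no measurable binding the
    estimate carries ``no_binding_flag``; mixed no-binding replicates are
    dropped with a warning.
    """
    if not replicates:
        raise ValueError("need at least one replicate series")
    ids = {s.antigen_id for s in replicates}
    if len(ids) != 1:
        raise ValueError(f"replicates mix antigen ids: {sorted(ids)}")
    antigen_id = ids.pop()
    fits = [friguet_kd(s) for s in replicates]
    kd_values = [f.kd for f in fits if not f.no_binding and f.kd is not None]
    if not kd_values:
        return KdEstimate(antigen_id=antigen_id, kd_values=[], kd_mean=None,
                          kd_sd=None, no_binding_flag=True)
    if len(kd_values) < len(fits):
        warnings.warn(
            f"{antigen_id}: {len(fits) - len(kd_values)} replicate(s) showed "
            f"no binding and were dropped from the aggregate"
        )
    mean = float(np.mean(kd_values))
    sd = float(np.std(kd_values, ddof=1)) if len(kd_values) > 1 else 0.0
    fold = None
    if reference is not None and reference.kd_mean:
        fold = mean / reference.kd_mean
    return KdEstimate(antigen_id=antigen_id, kd_values=kd_values,
                      kd_mean=mean, kd_sd=sd, fold_change_vs_reference=fold)


def simulate_elisa_series(
    kd_nm: float,
    antigen_id: str = "antigen",
    a0_grid_nm=DEFAULT_A0_GRID_NM,
    antibody_nm: float = DEFAULT_ANTIBODY_NM,
    a0_absorbance: float = 1.0,
    coating_nm: float | None = None,
    model: str = "large_excess",
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> ElisaSeries:
    """Synthetic absorbances from a 1:1 binding isotherm.

    ``model="large_excess"`` uses A = A0 * K_D / (K_D + a0) (free antigen
    ~ a0); ``model="exact"`` solves the binding quadratic.  Gaussian noise
    of ``noise_sd`` (absorbance units) is added when requested.
    """
    a0 = np.asarray(a0_grid_nm, dtype=float)
    if model == "large_excess":
        A = a0_absorbance * kd_nm / (kd_nm + a0)
    elif model == "exact":
        s = a0 + antibody_nm + kd_nm
        bound = (s - np.sqrt(s * s - 4.0 * a0 * antibody_nm)) / 2.0
        A = a0_absorbance * (1.0 - bound / antibody_nm)
    else:
        raise ValueError(f"unknown model {model!r}")
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        A = A + rng.normal(0.0, noise_sd, size=A.shape)
    return ElisaSeries(
        antigen_id=antigen_id,
        points=list(zip(a0.tolist(), A.tolist())),
        a0_absorbance=a0_absorbance,
        coating_conc=coating_nm,
        antibody_conc=antibody_nm,
    )


def load_elisa_csv(path: str) -> dict[str, list[ElisaSeries]]:
    """Read series from CSV columns (antigen_id, coating_nM, a0_nM, absorbance).

    Rows with ``a0_nM == 0`` encode the no-competitor absorbance A0 of
    their (antigen, coating) series.  Returns antigen_id -> list of series
    (one per coating concentration).
    """
    df = pd.read_csv(path)
    required = {"antigen_id", "coating_nM", "a0_nM", "absorbance"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ELISA CSV missing columns: {sorted(missing)}")
    out: dict[str, list[ElisaSeries]] = {}
    for (antigen, coating), grp in df.groupby(["antigen_id", "coating_nM"]):
        zero = grp[grp["a0_nM"] == 0]
        if len(zero) != 1:
            raise ValueError(
                f"{antigen} @ coating {coating} nM: need exactly one "
                f"a0_nM == 0 row for A0, got {len(zero)}"
            )
        pts = grp[grp["a0_nM"] > 0]
        series = ElisaSeries(
            antigen_id=str(antigen),
            points=list(zip(pts["a0_nM"].tolist(), pts["absorbance"].tolist())),
            a0_absorbance=float(zero["absorbance"].iloc[0]),
            coating_conc=float(coating),
        )
        out.setdefault(str(antigen), []).append(series)
    return out


def kd_table(
    estimates: list[KdEstimate], reference_id: str | None = None
) -> pd.DataFrame:
    """Summary table: K_D (nM) +/- SD and fold change versus the reference."""
    ref_mean = None
    if reference_id is not None:
        for e in estimates:
            if e.antigen_id == reference_id and e.kd_mean:
                ref_mean = e.kd_mean
    rows = []
    for e in estimates:
        fold = e.fold_change_vs_reference
        if fold is None and ref_mean and e.kd_mean:
            fold = e.kd_mean / ref_mean
        rows.append({
            "antigen_id": e.antigen_id,
            "kd_nM": e.kd_mean,
            "kd_sd_nM": e.kd_sd,
            "fold_change_vs_reference": fold,
            "no_binding": e.no_binding_flag,
        })
    return pd.DataFrame(rows)
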