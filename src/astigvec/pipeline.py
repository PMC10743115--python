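"""Per-eye DA computation, subgroup splitting, and aggregate accuracy tables.

For each eye and corneal measurement modality the difference in astigmatism
(DA) between refractive astigmatism (RA) and corneal astigmatism (CA) is
computed about the variable reference meridian phi = that eye's steep CA
meridian for that modality.  A modality's accuracy is summarized two ways:

* the *centroid* DA -- the net cylinder reconverted from the arithmetic
  means of the two polar-value components (vector mean, systematic error);
* the *mean DA magnitude* -- the average of the per-eye Euclidean DA
  magnitudes (arithmetic accuracy, ignores direction).

By the triangle inequality the centroid magnitude never exceeds the mean DA
magnitude.  Hypothesis testing is nonparametric throughout (the clinical
distributions fail normality screens): one- and two-sample Wilcoxon
signed-rank tests and the Friedman test across modalities.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import AxisClass, DAResult, NetAstigmatism, classify_axis, compute_da, polar_to_net, PolarValues

__all__ = [
    "ModalitySummary",
    "MagnitudeComparison",
    "eye_da_table",
    "summarize_modality",
    "compare_magnitudes",
    "split_by_axis_group",
    "wilcoxon_one_sample",
    "wilcoxon_paired",
    "friedman_test",
    "ks_normality_screen",
    "magnitude_matrix",
    "dkp_matrix",
    "summaries_frame",
]

logger = logging.getLogger(__name__)

#: Accuracy threshold for the "percentage within" column (inclusive).
WITHIN_THRESHOLD_D = 0.50

#: Below this group size, summaries are produced but p-values suppressed.
MIN_N_FOR_P = 5

_EXACT_N_MAX = 25


@dataclass(frozen=True)
class ModalitySummary:
    """Aggregate DA statistics for one modality (one table row)."""

    modality: str
    n: int
    mean_dkp_phi: float
    sd_dkp_phi: float
    mean_dkp_phi45: float
    sd_dkp_phi45: float
    centroid_da: NetAstigmatism
    mean_da_magnitude: float
    sd_da_magnitude: float
    da_range: tuple[float, float]
    pct_within_050: float
    p_dkp_phi_vs_zero: float | None
    p_dkp_phi45_vs_zero: float | None


@dataclass(frozen=True)
class MagnitudeComparison:
    """Scalar (direction-free) comparison of CA with RA magnitudes."""

    modality: str
    n: int
    mean_cyl: float
    sd_cyl: float
    mean_diff_with_ra: float
    sd_diff_with_ra: float
    p_value: float | None


def eye_da_table(records: Sequence, modality: str) -> list[DAResult]:
    """Per-eye DA for one modality; eyes missing the modality are skipped.

    The reference meridian varies per eye: it is the steep meridian of that
    eye's measurement by ``modality``.
    """
    das: list[DAResult] = []
    for r in records:
        ca = r.measurements.get(modality)
        if ca is None:
            logger.warning("eye %s lacks modality %s; skipped", r.eye_id, modality)
            continue
        das.append(compute_da(r.refractive_astigmatism, ca))
    return das


def wilcoxon_one_sample(values: Iterable[float], null_location: float = 0.0) -> float:
    """Two-sided one-sample Wilcoxon signed-rank p-value vs ``null_location``.

    Zero differences are dropped (Wilcoxon's original treatment) and tied
    absolute differences receive mid-ranks.  The exact null distribution is
    enumerated when the effective n is <= 25 and tie-free; otherwise the
    normal approximation with tie correction is used.  If every value equals
    the null location the test is vacuous: p = 1 with a warning.
    """
    d = np.asarray(list(values), dtype=float) - null_location
    d = d[d != 0.0]
    if d.size == 0:
        warnings.warn("all values equal the null location; Wilcoxon p set to 1")
        return 1.0
    ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= _EXACT_N_MAX and not ties) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided", method=method)
    return float(res.pvalue)


def wilcoxon_paired(x: Iterable[float], y: Iterable[float]) -> float:
    """Two-sample paired Wilcoxon signed-rank test (on the differences)."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    return wilcoxon_one_sample(x - y, 0.0)


def friedman_test(matrix: np.ndarray | pd.DataFrame) -> tuple[float, float]:
    """Friedman test across the columns of an eyes x treatments matrix.

    Returns ``(statistic, p)`` from the chi-square approximation with
    mid-ranks for ties.  A fully tied matrix (every row constant) carries no
    ranking information: statistic 0, p = 1.  Incomplete matrices are
    rejected -- no imputation.
    """
    a = np.asarray(matrix, dtype=float)
    if a.ndim != 2 or a.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least two treatment columns")
    if np.isnan(a).any():
        raise ValueError("incomplete matrix: missing cells are not imputed")
    if all(np.unique(row).size == 1 for row in a):
        return 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        stat, p = stats.friedmanchisquare(*(a[:, j] for j in range(a.shape[1])))
    if not np.isfinite(stat):
        return 0.0, 1.0
    return float(stat), float(p)


def ks_normality_screen(values: Iterable[float]) -> float:
    """One-sample Kolmogorov-Smirnov p-value against N(sample mean, sample SD).

    Advisory only: the pipeline always proceeds nonparametrically regardless
    of the outcome.  A zero-variance sample is maximally non-normal: p = 0
    with a warning.
    """
    x = np.asarray(list(values), dtype=float)
    if x.size < 8:
        raise ValueError("normality screen needs n >= 8")
    sd = x.std(ddof=1)
    if sd == 0.0:
        warnings.warn("degenerate (constant) sample; KS p set to 0")
        return 0.0
    return float(stats.kstest(x, "norm", args=(x.mean(), sd)).pvalue)


def summarize_modality(
    das: Sequence[DAResult], modality: str = "", *, min_n_for_p: int = MIN_N_FOR_P
) -> ModalitySummary:
    """Aggregate a modality's per-eye DA results into one summary row.

    Component means/SDs are arithmetic; the centroid is the net cylinder
    reconverted from the mean components (its meridian is relative to the
    per-eye reference phi); the mean DA magnitude averages per-eye
    magnitudes.  ``pct_within_050`` counts DA magnitude <= 0.50 D.
    """
    if len(das) == 0:
        raise ValueError("cannot summarize an empty DA table")
    dkp = np.array([d.delta_kp_phi for d in das])
    dkp45 = np.array([d.delta_kp_phi45 for d in das])
    mags = np.array([d.magnitude for d in das])
    n = len(das)
    centroid = polar_to_net(PolarValues(float(dkp.mean()), float(dkp45.mean()), 0.0))
    if n >= min_n_for_p:
        p_phi = wilcoxon_one_sample(dkp, 0.0) if np.any(dkp != 0) else 1.0
        p_phi45 = wilcoxon_one_sample(dkp45, 0.0) if np.any(dkp45 != 0) else 1.0
    else:
        logger.warning("n=%d < %d for %s: p-values suppressed", n, min_n_for_p, modality)
        p_phi = p_phi45 = None
    sd = lambda v: float(v.std(ddof=1)) if n > 1 else 0.0
    return ModalitySummary(
        modality=modality,
        n=n,
        mean_dkp_phi=float(dkp.mean()),
        sd_dkp_phi=sd(dkp),
        mean_dkp_phi45=float(dkp45.mean()),
        sd_dkp_phi45=sd(dkp45),
        centroid_da=centroid,
        mean_da_magnitude=float(mags.mean()),
        sd_da_magnitude=sd(mags),
        da_range=(float(mags.min()), float(mags.max())),
        pct_within_050=float(100.0 * np.mean(mags <= WITHIN_THRESHOLD_D)),
        p_dkp_phi_vs_zero=p_phi,
        p_dkp_phi45_vs_zero=p_phi45,
    )


def compare_magnitudes(records: Sequence, modality: str) -> MagnitudeComparison:
    """Direction-free comparison of CA vs RA cylinder magnitudes.

    The per-eye difference is RA magnitude - CA magnitude (negative when the
    corneal measurement reads larger than the refraction), tested with a
    paired two-sample Wilcoxon signed-rank test.
    """
    ra_mags, ca_mags = [], []
    for r in records:
        ca = r.measurements.get(modality)
        if ca is None:
            logger.warning("eye %s lacks modality %s; skipped", r.eye_id, modality)
            continue
        ra_mags.append(r.refractive_astigmatism.magnitude)
        ca_mags.append(ca.magnitude)
    if not ca_mags:
        raise ValueError(f"no eyes carry modality {modality}")
    ra_a, ca_a = np.array(ra_mags), np.array(ca_mags)
    diffs = ra_a - ca_a
    n = diffs.size
    if n >= MIN_N_FOR_P:
        p = wilcoxon_paired(ra_a, ca_a) if np.any(diffs != 0) else 1.0
    else:
        p = None
    return MagnitudeComparison(
        modality=modality,
        n=n,
        mean_cyl=float(ca_a.mean()),
        sd_cyl=float(ca_a.std(ddof=1)) if n > 1 else 0.0,
        mean_diff_with_ra=float(diffs.mean()),
        sd_diff_with_ra=float(diffs.std(ddof=1)) if n > 1 else 0.0,
        p_value=p,
    )


def split_by_axis_group(
    records: Sequence, grouping_modality: str = "auto_ka"
) -> dict[AxisClass, list]:
    """Partition eyes by the orientation class of the grouping modality's
    steep meridian (the automated keratometer, by convention)."""
    groups: dict[AxisClass, list] = {c: [] for c in AxisClass}
    for r in records:
        ca = r.measurements.get(grouping_modality)
        if ca is None:
            raise ValueError(f"eye {r.eye_id} lacks grouping modality {grouping_modality}")
        groups[classify_axis(ca.meridian)].append(r)
    return groups


def magnitude_matrix(
    records: Sequence, modalities: Sequence[str], *, include_ra: bool = False
) -> pd.DataFrame:
    """Complete eyes x modalities matrix of cylinder magnitudes.

    With ``include_ra`` the refractive cylinder joins as a first column --
    the variant of the across-measurements Friedman test that treats RA as
    one more treatment.  Eyes missing any requested modality are dropped (the
    Friedman test needs a complete block design).
    """
    cols = (["RA"] if include_ra else []) + list(modalities)
    rows = []
    for r in records:
        if any(m not in r.measurements for m in modalities):
            logger.warning("eye %s incomplete for matrix; dropped", r.eye_id)
            continue
        row = {}
        if include_ra:
            row["RA"] = r.refractive_astigmatism.magnitude
        for m in modalities:
            row[m] = r.measurements[m].magnitude
        rows.append(row)
    return pd.DataFrame(rows, columns=cols)


def dkp_matrix(
    records: Sequence, modalities: Sequence[str], component: str = "phi"
) -> pd.DataFrame:
    """Complete eyes x modalities matrix of a DA polar component.

    ``component`` is ``"phi"`` for delta KP(phi) or ``"phi45"`` for
    delta KP(phi+45); feeds the across-modalities Friedman test.
    """
    if component not in ("phi", "phi45"):
        raise ValueError("component must be 'phi' or 'phi45'")
    rows = []
    for r in records:
        if any(m not in r.measurements for m in modalities):
            logger.warning("eye %s incomplete for matrix; dropped", r.eye_id)
            continue
        ra = r.refractive_astigmatism
        row = {}
        for m in modalities:
            da = compute_da(ra, r.measurements[m])
            row[m] = da.delta_kp_phi if component == "phi" else da.delta_kp_phi45
        rows.append(row)
    return pd.DataFrame(rows, columns=list(modalities))


def summaries_frame(summaries: Sequence[ModalitySummary]) -> pd.DataFrame:
    """Flatten summaries into an accuracy table (one modality per row)."""
    return pd.DataFrame(
        {
            "modality": s.modality,
            "n": s.n,
            "mean_dkp_phi": s.mean_dkp_phi,
            "sd_dkp_phi": s.sd_dkp_phi,
            "p_dkp_phi_vs_zero": s.p_dkp_phi_vs_zero,
            "mean_dkp_phi45": s.mean_dkp_phi45,
            "sd_dkp_phi45": s.sd_dkp_phi45,
            "p_dkp_phi45_vs_zero": s.p_dkp_phi45_vs_zero,
            "centroid_da_mag": s.centroid_da.magnitude,
            "centroid_da_deg": s.centroid_da.meridian,
            "mean_da_magnitude": s.mean_da_magnitude,
            "sd_da_magnitude": s.sd_da_magnitude,
            "da_min": s.da_range[0],
            "da_max": s.da_range[1],
            "pct_within_050": s.pct_within_050,
        }
        for s in summaries
    )
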