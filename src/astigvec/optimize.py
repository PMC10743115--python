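"""Regression optimization of corneal astigmatism measurements.

Each corneal modality is optimized in retrospect by ordinary least squares
of the refractive polar value on the measured corneal cylinder and its
double-angle cosine,

    KP(phi)_RA = a + b * KP(phi)_CA + c * cos(2 * alpha)

where phi = alpha = the eye's steep corneal meridian for that modality (so
KP(phi)_CA is simply the corneal cylinder magnitude).  The intercept a and
slope b absorb magnitude calibration error; the cos(2 alpha) term absorbs
the orientation-dependent error that makes anterior-surface keratometry
overestimate with-the-rule and underestimate against-the-rule refractive
astigmatism (chiefly the unmeasured posterior cornea).

Replacing the measured KP(phi)_CA by the regression prediction zeroes the
mean delta KP(phi) in-sample (the OLS residual property) and shrinks its
spread; the oblique component delta KP(phi+45) is deliberately left
untouched -- the model assumes RA and CA share their meridian.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm

from .core import DAResult, NetAstigmatism, net_to_polar, compute_da
from .cohort import MODALITIES
from .pipeline import ModalitySummary, eye_da_table, summarize_modality, wilcoxon_paired

__all__ = [
    "RegressionModel",
    "OptimizationReport",
    "fit_optimization",
    "fit_all",
    "predict_kp_ra",
    "optimized_da",
    "compare_before_after",
    "PRESETS",
    "models_frame",
    "save_models",
    "load_models",
]


@dataclass(frozen=True)
class RegressionModel:
    """Coefficients of the optimization regression for one modality.

    ``a`` (D) intercept, ``b`` (dimensionless) slope on KP(phi)_CA, ``c``
    (D) coefficient on cos(2 alpha); ``bse`` are the OLS standard errors of
    (a, b, c) when fitted (None for literature presets).
    """

    modality: str
    a: float
    b: float
    c: float
    r_squared: float | None = None
    n_fit: int | None = None
    bse: tuple[float, float, float] | None = None

    def predict(self, ca_magnitude: float, steep_meridian: float) -> float:
        return predict_kp_ra(self, ca_magnitude, steep_meridian)


#: Literature coefficient sets, keyed by preset name then modality slug.
#: "pseudophakic_full" carries the fitted pseudophakic-cohort equations for all 14
#: modalities; the other presets are single published keratometry equations.
PRESETS: Mapping[str, Mapping[str, RegressionModel]] = {
    "pseudophakic_full": {
        m: RegressionModel(m, a, b, c, r_squared=r2)
        for m, (a, b, c, r2) in {
            "auto_ka": (-0.04, 0.92, 0.39, 0.76),
            "scheimpflug_ka": (-0.17, 0.99, 0.36, 0.81),
            "tcrp_2.0_pupil_zone": (-0.13, 0.78, 0.09, 0.50),
            "tcrp_2.0_apex_zone": (-0.23, 0.71, 0.04, 0.50),
            "tcrp_2.0_pupil_ring": (-0.22, 0.86, 0.07, 0.66),
            "tcrp_2.0_apex_ring": (-0.26, 0.90, 0.05, 0.66),
            "tcrp_3.0_pupil_zone": (-0.24, 0.91, 0.07, 0.69),
            "tcrp_3.0_apex_zone": (-0.22, 0.91, 0.09, 0.68),
            "tcrp_3.0_pupil_ring": (-0.24, 0.95, 0.14, 0.67),
            "tcrp_3.0_apex_ring": (-0.15, 0.84, 0.12, 0.68),
            "tcrp_4.0_pupil_zone": (-0.13, 0.93, 0.13, 0.77),
            "tcrp_4.0_apex_zone": (-0.16, 0.94, 0.15, 0.71),
            "tcrp_4.0_pupil_ring": (-0.29, 0.94, 0.27, 0.63),
            "tcrp_4.0_apex_ring": (-0.19, 0.86, 0.26, 0.65),
        }.items()
    },
    # Pseudophakic eye model of 184 eyes (keratometric index 1.3375).
    "bregnhoj_ka": {"auto_ka": RegressionModel("auto_ka", -0.09, 0.68, 0.33)},
    # Toric-IOL optimization of keratometry.
    "savini_toric_ka": {"auto_ka": RegressionModel("auto_ka", 0.103, 0.836, 0.457)},
}


def predict_kp_ra(model: RegressionModel, ca_magnitude: float, steep_meridian: float) -> float:
    """Predicted refractive polar value along the steep corneal meridian.

    ``a + b * M_CA + c * cos(2 * alpha)`` with a degree-based cosine.  The
    predicted net refractive astigmatism is this value along the same
    meridian (when positive).
    """
    return model.a + model.b * ca_magnitude + model.c * math.cos(math.radians(2.0 * steep_meridian))


def _design(records: Sequence, modality: str) -> tuple[np.ndarray, np.ndarray, list]:
    kept = [r for r in records if modality in r.measurements]
    y, rows = [], []
    for r in kept:
        ca = r.measurements[modality]
        y.append(net_to_polar(r.refractive_astigmatism, ca.meridian).kp_phi)
        rows.append([ca.magnitude, math.cos(math.radians(2.0 * ca.meridian))])
    return np.asarray(y), np.asarray(rows), kept


def fit_optimization(records: Sequence, modality: str) -> RegressionModel:
    """Fit the optimization regression for one modality by OLS.

    Requires >= 10 eyes carrying both a refraction and the modality.  A
    rank-deficient design (e.g. all steep meridians equal, making
    cos(2 alpha) constant) is rejected with the collinear column named.
    """
    y, X, kept = _design(records, modality)
    if len(kept) < 10:
        raise ValueError(f"need >= 10 eyes with modality {modality}, have {len(kept)}")
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < 3:
        names = ["KP(phi)_CA", "cos(2*alpha)"]
        for j, name in enumerate(names):
            if np.ptp(X[:, j]) == 0.0:
                raise np.linalg.LinAlgError(
                    f"design is rank-deficient: column '{name}' is constant"
                )
        raise np.linalg.LinAlgError("design is rank-deficient: collinear regressors")
    fit = sm.OLS(y, Xc).fit()
    a, b, c = (float(v) for v in fit.params)
    return RegressionModel(
        modality=modality,
        a=a,
        b=b,
        c=c,
        r_squared=float(fit.rsquared),
        n_fit=len(kept),
        bse=tuple(float(v) for v in fit.bse),
    )


def fit_all(records: Sequence, modalities: Sequence[str] = MODALITIES) -> dict[str, RegressionModel]:
    """Fit the optimization regression for every requested modality."""
    return {m: fit_optimization(records, m) for m in modalities}


def optimized_da(records: Sequence, model: RegressionModel) -> list[DAResult]:
    """Per-eye DA against the *optimized* corneal value.

    delta KP(phi) becomes the regression residual KP(phi)_RA - prediction;
    delta KP(phi+45) is carried over unchanged from the measured analysis.
    Eyes missing the model's modality are skipped, mirroring
    :func:`astigvec.pipeline.eye_da_table`.
    """
    out: list[DAResult] = []
    for r in records:
        ca = r.measurements.get(model.modality)
        if ca is None:
            continue
        measured = compute_da(r.refractive_astigmatism, ca)
        pred = predict_kp_ra(model, ca.magnitude, ca.meridian)
        dkp = net_to_polar(r.refractive_astigmatism, ca.meridian).kp_phi - pred
        dkp45 = measured.delta_kp_phi45
        ang = math.degrees(math.atan2(dkp45, dkp)) / 2.0 if (dkp, dkp45) != (0.0, 0.0) else 0.0
        out.append(
            DAResult(
                delta_kp_phi=dkp,
                delta_kp_phi45=dkp45,
                magnitude=math.hypot(dkp, dkp45),
                angle=ang % 180.0,
                reference=ca.meridian,
            )
        )
    return out


@dataclass(frozen=True)
class OptimizationReport:
    """Before/after accuracy of one modality under its fitted regression."""

    modality: str
    model: RegressionModel
    before: ModalitySummary
    after: ModalitySummary
    p_paired_dkp_phi: float
    p_paired_magnitude: float


def compare_before_after(
    records: Sequence, modality: str, model: RegressionModel | None = None
) -> OptimizationReport:
    """Measured-vs-optimized accuracy comparison for one modality.

    Pairs each eye's delta KP(phi) and DA magnitude before and after
    optimization under two-sample Wilcoxon signed-rank tests.  With
    ``model=None`` the regression is fitted in-sample first (the
    retrospective design), so the after-block mean delta KP(phi) is zero by
    the OLS residual property.
    """
    if model is None:
        model = fit_optimization(records, modality)
    before_das = eye_da_table(records, modality)
    after_das = optimized_da(records, model)
    if len(before_das) != len(after_das):
        raise ValueError("before/after tables misaligned")
    before = summarize_modality(before_das, modality)
    after = summarize_modality(after_das, modality)
    b_dkp = [d.delta_kp_phi for d in before_das]
    a_dkp = [d.delta_kp_phi for d in after_das]
    b_mag = [d.magnitude for d in before_das]
    a_mag = [d.magnitude for d in after_das]
# differences at float-noise scale are ties, not signal
    same = max(abs(x - y) for x, y in zip(b_dkp, a_dkp)) < 1e-10
    p_dkp = 1.0 if same else wilcoxon_paired(b_dkp, a_dkp)
    same_m = max(abs(x - y) for x, y in zip(b_mag, a_mag)) < 1e-10
    p_mag = 1.0 if same_m else wilcoxon_paired(b_mag, a_mag)
    return OptimizationReport(
        modality=modality,
        model=model,
        before=before,
        after=after,
        p_paired_dkp_phi=p_dkp,
        p_paired_magnitude=p_mag,
    )


def models_frame(models: Mapping[str, RegressionModel]):
    """Fitted-equation table: one modality per row with (a, b, c), r^2, n."""
    import pandas as pd

    return pd.DataFrame(
        {
            "modality": m.modality,
            "a": m.a,
            "b": m.b,
            "c": m.c,
            "r_squared": m.r_squared,
            "n_fit": m.n_fit,
        }
        for m in models.values()
    )


def save_models(models: Mapping[str, RegressionModel], path: str | Path) -> None:
    """Persist fitted models as JSON."""
    payload = {
        k: {"modality": m.modality, "a": m.a, "b": m.b, "c": m.c,
            "r_squared": m.r_squared, "n_fit": m.n_fit}
        for k, m in models.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_models(path: str | Path) -> dict[str, RegressionModel]:
    """Load models persisted by :func:`save_models`."""
    payload = json.loads(Path(path).read_text())
    return {k: RegressionModel(**v) for k, v in payload.items()}
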