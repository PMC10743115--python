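"""Synthetic pseudophakic cohorts with the structure the analysis assumes.

The clinical dataset behind this analysis is not public, so the generator
emulates its schema and statistical structure:

* each eye's *true* corneal astigmatism is a bivariate-Gaussian draw in
  double-angle space around a group centroid (with-the-rule, against-the-
  rule, or oblique, mixed 47.4 / 35.8 / 16.8 percent);
* each modality observes the true cylinder plus a per-modality bias
  (radial = magnitude over-reading, tangential = axis twist, applied in the
  eye's own steep-meridian frame) plus isotropic double-angle noise;
* refractive astigmatism follows the optimization-regression structure:
  KP(phi)_RA = a + b * M_CA + c * cos(2 phi) + noise about the true steep
  corneal meridian phi, with an independent zero-mean oblique component --
  so the regression stage has a well-defined truth to recover;
* IOL decentration and tilt are drawn uniformly inside the ranges observed
  clinically (all generated eyes pass the position filter).

Everything is reproducible from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import MODALITIES, EyeRecord
from .core import NetAstigmatism, normalize_meridian

__all__ = ["GeneratorConfig", "generate_cohort", "generate_worked_examples", "DEFAULT_MODALITY_BIAS"]

#: Default per-modality (radial, tangential) double-angle bias in dioptres,
#: chosen so the Scheimpflug modalities over-read cylinder magnitude relative
#: to automated keratometry on the scale seen clinically.
DEFAULT_MODALITY_BIAS: Mapping[str, tuple[float, float]] = {
    "auto_ka": (0.0, 0.0),
    "scheimpflug_ka": (0.09, 0.0),
    "tcrp_2.0_pupil_zone": (0.15, 0.0),
    "tcrp_2.0_apex_zone": (0.39, 0.0),
    "tcrp_2.0_pupil_ring": (0.20, 0.0),
    "tcrp_2.0_apex_ring": (0.21, 0.0),
    "tcrp_3.0_pupil_zone": (0.16, 0.0),
    "tcrp_3.0_apex_zone": (0.14, 0.0),
    "tcrp_3.0_pupil_ring": (0.13, 0.0),
    "tcrp_3.0_apex_ring": (0.14, 0.0),
    "tcrp_4.0_pupil_zone": (0.03, 0.0),
    "tcrp_4.0_apex_zone": (0.06, 0.0),
    "tcrp_4.0_pupil_ring": (0.21, 0.0),
    "tcrp_4.0_apex_ring": (0.18, 0.0),
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    Defaults reproduce the clinical cohort's marginals: 95 eyes, orientation
    mixture 0.474/0.358/0.168, corneal centroids of 0.65 D magnitude (steep
    at 90, 0 and 45 degrees for the three groups), and the automated-
    keratometry regression truth (a, b, c) = (-0.04, 0.92, 0.39) with
    residual noise 0.32 D along phi and 0.30 D along phi+45 -- which lands
    the mean refractive cylinder near 0.70 D.
    """

    n_eyes: int = 95
    seed: int = 0
    group_weights: tuple[float, float, float] = (0.474, 0.358, 0.168)  # WTR, ATR, OBL
    ca_centroids: tuple[tuple[float, float], ...] = ((-0.65, 0.0), (0.65, 0.0), (0.0, 0.65))
    ca_spread: float = 0.35
    true_coefficients: tuple[float, float, float] = (-0.04, 0.92, 0.39)
    modality_bias: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MODALITY_BIAS)
    )
    noise_sd_ra: float = 0.32
    noise_sd_ra_cross: float = 0.30
    noise_sd_ca: float = 0.10
    modalities: tuple[str, ...] = MODALITIES
    dec_h_range: tuple[float, float] = (0.0, 0.38)
    dec_v_range: tuple[float, float] = (0.0, 0.35)
    dec_total_max: float = 0.39
    tilt_h_range: tuple[float, float] = (0.0, 3.0)
    tilt_v_range: tuple[float, float] = (0.0, 3.5)

    def __post_init__(self) -> None:
        if self.n_eyes < 1:
            raise ValueError("n_eyes must be >= 1")
        if abs(sum(self.group_weights) - 1.0) > 1e-9 or any(
            w < 0 for w in self.group_weights
        ):
            raise ValueError("group_weights must be nonnegative and sum to 1")
        for name, v in (
            ("ca_spread", self.ca_spread),
            ("noise_sd_ra", self.noise_sd_ra),
            ("noise_sd_ra_cross", self.noise_sd_ra_cross),
            ("noise_sd_ca", self.noise_sd_ca),
        ):
            if v < 0:
                raise ValueError(f"{name} must be >= 0")
        unknown = set(self.modalities) - set(MODALITIES)
        if unknown:
            raise ValueError(f"unknown modalities {sorted(unknown)}")


def _net_from_xy(x: float, y: float) -> NetAstigmatism:
    m = math.hypot(x, y)
    if m == 0.0:
        return NetAstigmatism(0.0, 0.0)
    return NetAstigmatism(m, normalize_meridian(math.degrees(math.atan2(y, x)) / 2.0))


def generate_cohort(
    config: GeneratorConfig, *, return_groups: bool = False
) -> list[EyeRecord] | tuple[list[EyeRecord], np.ndarray]:
    """Draw a fully reproducible synthetic cohort under ``config``.

    With ``return_groups`` the assigned mixture components (0 = WTR, 1 = ATR,
    2 = oblique) are returned alongside the records.  Note that the class an
    analysis assigns from the *observed* automated-keratometry meridian can
    differ near the class boundaries (spread and measurement noise leak a few
    percent of eyes, mostly into the oblique class).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_eyes
    a, b, c = config.true_coefficients
    groups = rng.choice(3, size=n, p=np.asarray(config.group_weights))
    centroids = np.asarray(config.ca_centroids, dtype=float)

    # true corneal astigmatism in double-angle space
    true_xy = centroids[groups] + rng.normal(0.0, config.ca_spread, size=(n, 2))
    true_mag = np.hypot(true_xy[:, 0], true_xy[:, 1])
    true_mer = (np.degrees(np.arctan2(true_xy[:, 1], true_xy[:, 0])) / 2.0) % 180.0

    # refractive astigmatism about the true steep corneal meridian
    kp_ra = (
        a
        + b * true_mag
        + c * np.cos(np.radians(2.0 * true_mer))
        + rng.normal(0.0, config.noise_sd_ra, size=n)
    )
    kp45_ra = rng.normal(0.0, config.noise_sd_ra_cross, size=n)
    # rotate (kp, kp45) from the eye frame into absolute double-angle space
    two_phi = np.radians(2.0 * true_mer)
    ra_x = kp_ra * np.cos(two_phi) - kp45_ra * np.sin(two_phi)
    ra_y = kp_ra * np.sin(two_phi) + kp45_ra * np.cos(two_phi)

    # observed modalities: eye-frame bias plus isotropic noise
    obs: dict[str, np.ndarray] = {}
    for m in config.modalities:
        radial, tangential = config.modality_bias.get(m, (0.0, 0.0))
        bias_x = radial * np.cos(two_phi) - tangential * np.sin(two_phi)
        bias_y = radial * np.sin(two_phi) + tangential * np.cos(two_phi)
        noise = rng.normal(0.0, config.noise_sd_ca, size=(n, 2))
        obs[m] = true_xy + np.column_stack([bias_x, bias_y]) + noise

    spherical_equivalent = rng.normal(0.0, 0.5, size=n)

    # IOL position: uniform within clinical ranges, resampled until the
    # decentration vector total stays inside its observed maximum
    dec_h = rng.uniform(*config.dec_h_range, size=n) * rng.choice([-1.0, 1.0], size=n)
    dec_v = rng.uniform(*config.dec_v_range, size=n) * rng.choice([-1.0, 1.0], size=n)
    while True:
        bad = np.hypot(dec_h, dec_v) > config.dec_total_max
        if not bad.any():
            break
        k = int(bad.sum())
        dec_h[bad] = rng.uniform(*config.dec_h_range, size=k) * rng.choice([-1.0, 1.0], size=k)
        dec_v[bad] = rng.uniform(*config.dec_v_range, size=k) * rng.choice([-1.0, 1.0], size=k)
    tilt_h = rng.uniform(*config.tilt_h_range, size=n) * rng.choice([-1.0, 1.0], size=n)
    tilt_v = rng.uniform(*config.tilt_v_range, size=n) * rng.choice([-1.0, 1.0], size=n)

    records: list[EyeRecord] = []
    width = len(str(n))
    for i in range(n):
        ra = _net_from_xy(ra_x[i], ra_y[i])
        measurements = {m: _net_from_xy(*obs[m][i]) for m in config.modalities}
        records.append(
            EyeRecord(
                eye_id=f"syn{i + 1:0{width}d}",
                ref_sphere=float(spherical_equivalent[i] - ra.magnitude / 2.0),
                ref_cyl=ra.magnitude,
                ref_axis=ra.meridian,
                measurements=measurements,
                dec_h=float(dec_h[i]),
                dec_v=float(dec_v[i]),
                dec_total=float(np.hypot(dec_h[i], dec_v[i])),
                tilt_h=float(tilt_h[i]),
                tilt_v=float(tilt_v[i]),
            )
        )
    if return_groups:
        return records, groups
    return records


def generate_worked_examples(path: str | Path | None = None) -> pd.DataFrame:
    """Deterministic fixture cylinders for hand-checkable calculations.

    Contains the two canonical regression inputs (1.0 D @ 90, the
    with-the-rule case predicting 0.49 D, and 1.0 D @ 0, the against-the-
    rule case predicting 1.27 D under the automated-keratometry preset), the
    3-4-5 polar-value pair, and the orientation-class boundary meridians.
    Regeneration is byte-identical; ``path`` optionally writes the CSV.
    """
    rows = [
        ("wtr_unit", "regression_input", 1.0, 90.0, "predicts 0.49 D under auto_ka preset"),
        ("atr_unit", "regression_input", 1.0, 0.0, "predicts 1.27 D under auto_ka preset"),
        ("pyth_345", "polar_fixture", 0.5, 26.565051177077994, "polar values (0.3, 0.4) about 0"),
        ("wtr_low", "axis_boundary", 1.0, 61.0, "lowest WTR meridian"),
        ("wtr_high", "axis_boundary", 1.0, 120.0, "highest WTR meridian"),
        ("atr_high", "axis_boundary", 1.0, 30.0, "highest low-side ATR meridian"),
        ("atr_low", "axis_boundary", 1.0, 151.0, "lowest high-side ATR meridian"),
        ("obl_low", "axis_boundary", 1.0, 31.0, "lowest oblique meridian"),
        ("obl_high", "axis_boundary", 1.0, 150.0, "highest oblique meridian"),
        ("zero_cyl", "degenerate", 0.0, 0.0, "zero cylinder carries meridian 0"),
    ]
    df = pd.DataFrame(rows, columns=["name", "kind", "magnitude", "meridian", "note"])
    if path is not None:
        df.to_csv(path, index=False)
    return df


def identity_config(n_eyes: int = 95, seed: int = 0, **overrides) -> GeneratorConfig:
    """A noise-free, bias-free, identity-regression configuration.

    Every modality then observes the true cylinder exactly and the
    refraction equals it, so the whole pipeline yields all-zero DA -- the
    canonical closure check.
    """
    cfg = GeneratorConfig(
        n_eyes=n_eyes,
        seed=seed,
        true_coefficients=(0.0, 1.0, 0.0),
        modality_bias={m: (0.0, 0.0) for m in MODALITIES},
        noise_sd_ra=0.0,
        noise_sd_ra_cross=0.0,
        noise_sd_ca=0.0,
    )
    return replace(cfg, **overrides) if overrides else cfg
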