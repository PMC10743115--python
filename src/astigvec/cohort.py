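"""Eye-record tables: CSV schema, validation, and the IOL-position filter.

Schema (one row per eye, RFC-4180 CSV, UTF-8, header required)::

    eye_id, ref_sphere, ref_cyl, ref_axis,
    dec_h, dec_v, dec_total, tilt_h, tilt_v,
    {modality}_mag, {modality}_axis   # per modality slug, e.g. tcrp_4.0_pupil_zone

Modalities are the automated keratometer, Scheimpflug keratometry, and
Scheimpflug total corneal refractive power (TCRP) at 2.0/3.0/4.0 mm, each
centred on the pupil or the corneal apex and averaged over a zone (disc) or
ring (annulus) -- 14 measurements in total.  Missing modality cells are
empty, never zero: a zero cylinder is a measurement, an empty cell is not.

Decentration signs (temporal/nasal, superior/inferior) are stored as given,
but only absolute values and the vector total enter the analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import NetAstigmatism, normalize_meridian

__all__ = [
    "MODALITIES",
    "EyeRecord",
    "CohortValidationError",
    "refraction_to_net",
    "read_cohort",
    "write_cohort",
    "filter_iol_position",
    "DECENTRATION_LIMIT_MM",
    "TILT_LIMIT_DEG",
]

logger = logging.getLogger(__name__)

#: Canonical modality slugs, in table order.
MODALITIES: tuple[str, ...] = ("auto_ka", "scheimpflug_ka") + tuple(
    f"tcrp_{diam}_{center}_{mode}"
    for diam in ("2.0", "3.0", "4.0")
    for center in ("pupil", "apex")
    for mode in ("zone", "ring")
)

#: Exclusion thresholds: eyes with decentration > 0.4 mm or tilt > 5 deg are
#: excluded (strict inequalities; the boundary values pass).
DECENTRATION_LIMIT_MM = 0.4
TILT_LIMIT_DEG = 5.0

_BASE_COLUMNS = (
    "eye_id",
    "ref_sphere",
    "ref_cyl",
    "ref_axis",
    "dec_h",
    "dec_v",
    "dec_total",
    "tilt_h",
    "tilt_v",
)

_TOTAL_DEC_TOL = 0.02  # mm; admits clinically rounded totals


class CohortValidationError(ValueError):
    """A cohort table violated the schema; the message names row and column."""


@dataclass(frozen=True)
class EyeRecord:
    """One pseudophakic eye: refraction, corneal measurements, IOL position."""

    eye_id: str
    ref_sphere: float
    ref_cyl: float
    ref_axis: float
    measurements: Mapping[str, NetAstigmatism] = field(default_factory=dict)
    dec_h: float = 0.0
    dec_v: float = 0.0
    dec_total: float = 0.0
    tilt_h: float = 0.0
    tilt_v: float = 0.0

    @property
    def refractive_astigmatism(self) -> NetAstigmatism:
        return refraction_to_net(self.ref_sphere, self.ref_cyl, self.ref_axis)


def refraction_to_net(
    sphere: float, cylinder: float, axis: float, *, axis_is_steep: bool = True
) -> NetAstigmatism:
    """Map a plus-cylinder refraction (S, C, axis) to a net cylinder M @ alpha.

    For myopic astigmatism written in plus-cylinder form the cylinder axis
    coincides with the steep (more myopic) meridian, so by default
    ``M = C, alpha = axis``.  ``axis_is_steep=False`` selects the opposite
    convention (steep meridian perpendicular to the recorded axis); the
    choice is a recording convention of the refraction, not a property of
    the eye.
    """
    if cylinder < 0:
        raise ValueError("plus-cylinder refraction requires cylinder >= 0")
    alpha = normalize_meridian(axis if axis_is_steep else axis + 90.0)
    return NetAstigmatism(cylinder, alpha if cylinder > 0 else 0.0)


def _check_axis(value: float, row: int, col: str) -> float:
    if not (0.0 <= value <= 180.0):
        raise CohortValidationError(
            f"row {row}: column '{col}' axis {value} out of range [0, 180]"
        )
    return normalize_meridian(value)


def _check_mag(value: float, row: int, col: str) -> float:
    if not (value >= 0.0):
        raise CohortValidationError(f"row {row}: column '{col}' magnitude {value} < 0")
    return float(value)


def read_cohort(path: str | Path) -> list[EyeRecord]:
    """Read and validate a cohort CSV; one :class:`EyeRecord` per row.

    Missing modality cells become absent entries in ``measurements``.
    Raises :class:`CohortValidationError` naming the offending row/column on
    malformed data, and listing the valid modality slugs on an unknown
    modality column.
    """
    df = pd.read_csv(path, dtype={"eye_id": str})
    missing = [c for c in _BASE_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"missing required columns: {missing}")
    known = set(_BASE_COLUMNS) | {
        f"{m}_{suffix}" for m in MODALITIES for suffix in ("mag", "axis")
    }
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise CohortValidationError(
            f"unknown columns {unknown}; valid modality slugs are {list(MODALITIES)}"
        )
    records: list[EyeRecord] = []
    for i, row in df.iterrows():
        rowno = int(i) + 2  # 1-based with header line
        if pd.isna(row["eye_id"]) or str(row["eye_id"]).strip() == "":
            raise CohortValidationError(f"row {rowno}: empty eye_id")
        for col in _BASE_COLUMNS[1:]:
            if pd.isna(row[col]):
                raise CohortValidationError(f"row {rowno}: column '{col}' is empty")
        ref_cyl = _check_mag(float(row["ref_cyl"]), rowno, "ref_cyl")
        ref_axis = _check_axis(float(row["ref_axis"]), rowno, "ref_axis")
        dec_h, dec_v, dec_total = (
            float(row["dec_h"]),
            float(row["dec_v"]),
            float(row["dec_total"]),
        )
        if abs(math.hypot(dec_h, dec_v) - dec_total) > _TOTAL_DEC_TOL:
            raise CohortValidationError(
                f"row {rowno}: dec_total {dec_total} inconsistent with "
                f"sqrt(dec_h^2 + dec_v^2) = {math.hypot(dec_h, dec_v):.4f}"
            )
        measurements: dict[str, NetAstigmatism] = {}
        for m in MODALITIES:
            mag_col, axis_col = f"{m}_mag", f"{m}_axis"
            if mag_col not in df.columns:
                continue
            mag_v, axis_v = row[mag_col], row.get(axis_col)
            if pd.isna(mag_v) and (axis_v is None or pd.isna(axis_v)):
                continue  # absent measurement
            if pd.isna(mag_v) or axis_v is None or pd.isna(axis_v):
                raise CohortValidationError(
                    f"row {rowno}: modality '{m}' has only one of magnitude/axis"
                )
            mag = _check_mag(float(mag_v), rowno, mag_col)
            ax = _check_axis(float(axis_v), rowno, axis_col)
            measurements[m] = NetAstigmatism(mag, ax if mag > 0 else 0.0)
        records.append(
            EyeRecord(
                eye_id=str(row["eye_id"]),
                ref_sphere=float(row["ref_sphere"]),
                ref_cyl=ref_cyl,
                ref_axis=ref_axis,
                measurements=measurements,
                dec_h=dec_h,
                dec_v=dec_v,
                dec_total=dec_total,
                tilt_h=float(row["tilt_h"]),
                tilt_v=float(row["tilt_v"]),
            )
        )
    return records


def write_cohort(records: Sequence[EyeRecord], path: str | Path) -> None:
    """Write records to the cohort CSV schema (inverse of :func:`read_cohort`)."""
    rows = []
    for r in records:
        row: dict[str, object] = {
            "eye_id": r.eye_id,
            "ref_sphere": r.ref_sphere,
            "ref_cyl": r.ref_cyl,
            "ref_axis": r.ref_axis,
            "dec_h": r.dec_h,
            "dec_v": r.dec_v,
            "dec_total": r.dec_total,
            "tilt_h": r.tilt_h,
            "tilt_v": r.tilt_v,
        }
        for m in MODALITIES:
            net = r.measurements.get(m)
            row[f"{m}_mag"] = net.magnitude if net is not None else None
            row[f"{m}_axis"] = net.meridian if net is not None else None
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def filter_iol_position(
    records: Iterable[EyeRecord],
    *,
    decentration_limit: float = DECENTRATION_LIMIT_MM,
    tilt_limit: float = TILT_LIMIT_DEG,
) -> tuple[list[EyeRecord], list[tuple[str, str]]]:
    """Partition records by the IOL position criterion.

    Kept iff total decentration <= ``decentration_limit`` (mm) and the larger
    absolute per-axis tilt <= ``tilt_limit`` (degrees); exclusions carry a
    machine-readable reason and are logged.
    """
    kept: list[EyeRecord] = []
    excluded: list[tuple[str, str]] = []
    for r in records:
        reasons = []
        if r.dec_total > decentration_limit:
            reasons.append(f"decentration {r.dec_total:.3f} mm > {decentration_limit}")
        if max(abs(r.tilt_h), abs(r.tilt_v)) > tilt_limit:
            reasons.append(
                f"tilt {max(abs(r.tilt_h), abs(r.tilt_v)):.2f} deg > {tilt_limit}"
            )
        if reasons:
            reason = "; ".join(reasons)
            logger.info("excluding eye %s: %s", r.eye_id, reason)
            excluded.append((r.eye_id, reason))
        else:
            kept.append(r)
    return kept, excluded
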