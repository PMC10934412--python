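"""Logarithmic cellular-uptake model.

Across particle loads p spanning roughly 8–160 ug/mL, the percentage of
particle-positive cells U_P grows degressively and is well described by

    U_P = u_S * log10(p_tilde) + u_L

with p_tilde = (p * solid_measured / solid_theoretical) / p0 the dimensionless
particle load corrected by the gravimetric solid-content determination and
normalized by the arbitrary standard load p0 = 1 ug/mL.  u_S (slope, % per
decade of load) measures how fast uptake saturates with dose; u_L (level, %)
is the uptake at p_tilde = 1.  Each (sample, cell line) series is fit by
linear regression of U_P on log10(p_tilde); series with R^2 < 0.80 are
excluded from further analysis.  The fit also reports U_P at a reference load
of 100 ug/mL, capped into [0, 100] % for reporting (raw value retained).

Phagocytic macrophage-like RAW264.7 cells show high, weakly composition-
dependent uptake; nonphagocytic HEK cells take particles up by endocytosis
with a strong dependence on the styrene content x.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import ParticleRecord, UptakeMeasurement, group_uptake

logger = logging.getLogger(__name__)

__all__ = [
    "UptakeFit",
    "correct_load",
    "fit_uptake",
    "fit_all_uptake",
    "summarize_uptake",
    "uptake_feature_table",
    "fits_to_frame",
    "R2_EXCLUSION_THRESHOLD",
    "REFERENCE_LOAD",
    "STANDARD_LOAD_P0",
]

#: Series with model correlation R^2 strictly below this are excluded.
R2_EXCLUSION_THRESHOLD = 0.80
#: Nominal particle load (ug/mL) at which U_P is reported.
REFERENCE_LOAD = 100.0
#: Arbitrary standard particle load p0 (ug/mL) making p_tilde dimensionless.
STANDARD_LOAD_P0 = 1.0


@dataclass
class UptakeFit:
    """Fitted uptake parameters for one (sample, cell line) series.

    ``u_p_ref`` is the reported U_P at the reference load, capped into
    [0, 100] %, and ``None`` when the series is excluded (R^2 below
    threshold); ``u_p_ref_raw`` keeps the uncapped model value regardless.
    ``expected_error`` (Er, %) is the replicate-derived expected error of the
    uptake measurements (pooled within-load sd), ``None`` without replicates.
    """

    sample_id: str
    cell_line: str
    u_s: float
    u_l: float
    r_squared: float
    excluded: bool
    u_p_ref: float | None
    u_p_ref_raw: float
    expected_error: float | None
    n_points: int


def correct_load(
    p: float,
    solid_theoretical: float | None = None,
    solid_measured: float | None = None,
    p0: float = STANDARD_LOAD_P0,
):
    """Dimensionless corrected load p_tilde = (p * measured/theoretical) / p0.

    A missing measured solid content defaults to the theoretical one (no
    correction).  All inputs must be positive.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or p0 <= 0:
        raise ValueError("particle loads and p0 must be > 0")
    if solid_measured is not None and solid_theoretical is None:
        raise ValueError("solid_measured given without solid_theoretical")
    factor = 1.0
    if solid_theoretical is not None:
        if solid_theoretical <= 0:
            raise ValueError("solid_theoretical must be > 0")
        if solid_measured is None:
            solid_measured = solid_theoretical
        if solid_measured <= 0:
            raise ValueError("solid_measured must be > 0")
        factor = solid_measured / solid_theoretical
    out = p * factor / p0
    return float(out) if out.ndim == 0 else out


def fit_uptake(
    measurements: Sequence[UptakeMeasurement],
    r2_threshold: float = R2_EXCLUSION_THRESHOLD,
    reference_load: float = REFERENCE_LOAD,
    p0: float = STANDARD_LOAD_P0,
    solid_theoretical: float | None = None,
    solid_measured: float | None = None,
    log_base: float = 10.0,
) -> UptakeFit:
    """Fit U_P = u_S log10(p_tilde) + u_L for one (sample, cell line) series.

    Measurements carrying a precomputed ``load_corrected`` use it; otherwise
    p_tilde is computed from the nominal load and solid contents.  Requires at
    least 3 distinct loads; replicate measurements at the same load are used
    both in the regression and to derive the expected error Er.
    """
    if not measurements:
        raise ValueError("no measurements")
    keys = {(m.sample_id, m.cell_line) for m in measurements}
    if len(keys) > 1:
        raise ValueError(f"measurements span multiple (sample, cell) series: {keys}")
    sample_id, cell_line = next(iter(keys))
    loads = np.array([m.load_p for m in measurements])
    if len(set(loads.tolist())) < 3:
        raise ValueError(
            f"{sample_id}/{cell_line}: need >= 3 distinct loads, "
            f"have {len(set(loads.tolist()))}"
        )
    p_tilde = np.array(
        [
            m.load_corrected
            if m.load_corrected is not None
            else correct_load(m.load_p, solid_theoretical, solid_measured, p0)
            for m in measurements
        ]
    )
    u_p = np.array([m.positive_pct for m in measurements])
    logp = np.log10(p_tilde) / math.log10(log_base)
    # slope/intercept via least squares; R^2 handled explicitly so that an
    # exactly flat, exactly fitted series (zero total and residual variance)
    # counts as a perfect fit rather than dividing 0/0
    slope, intercept = np.polyfit(logp, u_p, 1)
    resid = u_p - (slope * logp + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((u_p - u_p.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res <= 1e-20 else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    excluded = r2 < r2_threshold
    ref_tilde = correct_load(reference_load, solid_theoretical, solid_measured, p0)
    ref_raw = float(slope * (math.log10(ref_tilde) / math.log10(log_base)) + intercept)
    ref = float(min(max(ref_raw, 0.0), 100.0))
    er = _replicate_error(loads, u_p)
    return UptakeFit(
        sample_id=sample_id,
        cell_line=cell_line,
        u_s=float(slope),
        u_l=float(intercept),
        r_squared=float(r2),
        excluded=bool(excluded),
        u_p_ref=None if excluded else ref,
        u_p_ref_raw=ref_raw,
        expected_error=er,
        n_points=len(measurements),
    )


def _replicate_error(loads: np.ndarray, u_p: np.ndarray) -> float | None:
    """Pooled within-load replicate sd of U_P (first-order propagation: the
    model is linear in U_P, so replicate scatter passes through unchanged)."""
    variances = []
    for load in np.unique(loads):
        vals = u_p[loads == load]
        if len(vals) >= 2:
            variances.append(np.var(vals, ddof=1))
    if not variances:
        return None
    return float(np.sqrt(np.mean(variances)))


def fit_all_uptake(
    measurements: Iterable[UptakeMeasurement],
    records: Iterable[ParticleRecord] | None = None,
    **kwargs,
) -> list[UptakeFit]:
    """Fit every (sample, cell line) series; solid contents taken from records.

    Series failing the >= 3 distinct loads requirement are skipped with a log
    entry rather than aborting the cohort.
    """
    solids: dict[str, tuple[float | None, float | None]] = {}
    if records is not None:
        solids = {
            r.sample_id: (r.solid_theoretical, r.solid_measured) for r in records
        }
    fits = []
    for (sample_id, cell_line), group in group_uptake(measurements).items():
        st, sm_ = solids.get(sample_id, (None, None))
        try:
            fits.append(
                fit_uptake(group, solid_theoretical=st, solid_measured=sm_, **kwargs)
            )
        except ValueError as exc:
            logger.warning("skipping %s/%s: %s", sample_id, cell_line, exc)
    return fits


def summarize_uptake(fits: Iterable[UptakeFit], cell_line: str) -> dict[str, float]:
    """Cohort mean and sample sd of U_P at the reference load.

    Only non-excluded fits with a reported U_P enter; the capped value is used
    as reported (a series capped at 100 % counts as 100).
    """
    vals = [
        f.u_p_ref for f in fits if f.cell_line == cell_line and not f.excluded
        and f.u_p_ref is not None
    ]
    if len(vals) < 2:
        raise ValueError(
            f"need >= 2 non-excluded fits for {cell_line}, have {len(vals)}"
        )
    arr = np.asarray(vals, dtype=float)
    return {
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)),
        "n": int(len(arr)),
    }


def fits_to_frame(fits: Sequence[UptakeFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": f.sample_id,
                "cell_line": f.cell_line,
                "u_s": f.u_s,
                "u_l": f.u_l,
                "r_squared": f.r_squared,
                "excluded": f.excluded,
                "u_p_ref": f.u_p_ref,
                "u_p_ref_raw": f.u_p_ref_raw,
                "expected_error": f.expected_error,
                "n_points": f.n_points,
            }
            for f in fits
        ]
    )


def uptake_feature_table(
    fits: Iterable[UptakeFit], records: Iterable[ParticleRecord]
) -> pd.DataFrame:
    """Merge uptake fits with particle properties for the uptake PCA/MLR.

    One row per sample with columns x (mol %), Mn^2 (kg^2/mol^2), d (nm, DLS),
    -z (mV), U_P(RAW) and U_P(HEK) (%, at the reference load).  Rows missing
    any variable (e.g. an excluded cell-line fit) are dropped and logged.
    """
    records = list(records)
    fits = list(fits)
    rec_ids = {r.sample_id for r in records}
    fit_ids = {f.sample_id for f in fits}
    if not rec_ids & fit_ids:
        raise ValueError("no overlapping sample_ids between fits and records")
    up: dict[str, dict[str, float]] = {}
    for f in fits:
        if not f.excluded and f.u_p_ref is not None:
            up.setdefault(f.sample_id, {})[f.cell_line] = f.u_p_ref
    rows = []
    for r in records:
        if r.sample_id not in fit_ids:
            continue
        rows.append(
            {
                "sample_id": r.sample_id,
                "x": r.x_sty,
                "Mn^2": r.mn**2,
                "d": r.d_dls,
                "-z": r.minus_z,
                "U_P(RAW)": up.get(r.sample_id, {}).get("RAW"),
                "U_P(HEK)": up.get(r.sample_id, {}).get("HEK"),
            }
        )
    df = pd.DataFrame(rows).set_index("sample_id")
    n0 = len(df)
    out = df.dropna()
    if n0 - len(out):
        logger.info(
            "uptake_feature_table: dropped %d of %d samples with missing variables",
            n0 - len(out),
            n0,
        )
    return out
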