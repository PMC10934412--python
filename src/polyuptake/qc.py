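"""Size quality control from paired DLS/SEM diameters.

DLS reports an intensity-weighted hydrodynamic diameter and is very sensitive
to aggregates in suspension; SEM gives a number-weighted dry-state diameter
that is blind to solution aggregation.  The ratio r = d(DLS)/d(SEM) therefore
separates well-dispersed samples (r near 1) from samples that aggregated
during the DLS measurement (r > 1.2) and from samples whose DLS size is
over-approximated by broad dispersity (r < 0.8).  Independently, DLS diameters
below 800 nm were verified to be single particles by randomized SEM
examination, so the single-particle flag uses a strict d(DLS) < 800 nm rule.

This module also provides a redundancy screen (pairwise Pearson correlation)
used to drop non-independent variables — e.g. the PdI, which tracks the DLS
diameter through aggregation — before multivariate analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import ParticleRecord

__all__ = [
    "DispersionClass",
    "QCRecord",
    "dls_sem_ratio",
    "round_ratio",
    "classify_dispersion",
    "flag_single_particles",
    "qc_frame",
    "screen_redundant_variables",
    "SINGLE_PARTICLE_THRESHOLD_NM",
    "AGGREGATION_RATIO",
    "OVERAPPROXIMATION_RATIO",
]

#: Strict DLS-diameter threshold below which samples count as single particles.
SINGLE_PARTICLE_THRESHOLD_NM = 800.0
#: r strictly above this flags aggregate formation during DLS.
AGGREGATION_RATIO = 1.2
#: r strictly below this flags size over-approximation from broad dispersity.
OVERAPPROXIMATION_RATIO = 0.8


class DispersionClass(str, Enum):
    CONSISTENT = "consistent"
    AGGREGATED = "aggregated"
    OVER_APPROXIMATED = "over_approximated"
    UNKNOWN = "unknown"


@dataclass
class QCRecord:
    """QC verdict for one sample.

    ``ratio_r`` is stored at full precision; use :func:`round_ratio` for the
    1-decimal presentation used in characterization tables.
    """

    sample_id: str
    ratio_r: float | None
    dispersion_class: DispersionClass
    single_particle: bool
    exclude_from_size_model: bool


def dls_sem_ratio(d_dls: float, d_sem: float | None) -> float | None:
    """r = d(DLS)/d(SEM); ``None`` when the SEM diameter is missing."""
    if d_sem is None or (isinstance(d_sem, float) and np.isnan(d_sem)):
        return None
    if d_dls <= 0 or d_sem <= 0:
        raise ValueError(f"diameters must be > 0, got d_dls={d_dls}, d_sem={d_sem}")
    return d_dls / d_sem


def round_ratio(ratio: float, decimals: int = 1) -> float:
    """Half-up rounding for display (1.25 -> 1.3), as in printed size tables."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(ratio)).quantize(q, rounding=ROUND_HALF_UP))


def classify_dispersion(ratio: float | None) -> DispersionClass:
    """Classify a DLS/SEM ratio; boundary values (0.8, 1.2) count as consistent."""
    if ratio is None or (isinstance(ratio, float) and np.isnan(ratio)):
        return DispersionClass.UNKNOWN
    if ratio <= 0:
        raise ValueError(f"ratio must be > 0, got {ratio}")
    if ratio > AGGREGATION_RATIO:
        return DispersionClass.AGGREGATED
    if ratio < OVERAPPROXIMATION_RATIO:
        return DispersionClass.OVER_APPROXIMATED
    return DispersionClass.CONSISTENT


def flag_single_particles(
    records: Iterable[ParticleRecord],
    threshold_nm: float = SINGLE_PARTICLE_THRESHOLD_NM,
) -> list[QCRecord]:
    """Full QC pass: ratio, dispersion class, single-particle and exclusion flags.

    A sample is excluded from the micellar size model when it aggregated during
    DLS or is not a single particle (d_dls >= threshold, strict inequality for
    the single-particle side).
    """
    if threshold_nm <= 0:
        raise ValueError("threshold_nm must be > 0")
    out = []
    for r in records:
        ratio = dls_sem_ratio(r.d_dls, r.d_sem)
        cls = classify_dispersion(ratio)
        single = r.d_dls < threshold_nm
        out.append(
            QCRecord(
                sample_id=r.sample_id,
                ratio_r=ratio,
                dispersion_class=cls,
                single_particle=single,
                exclude_from_size_model=(cls is DispersionClass.AGGREGATED)
                or not single,
            )
        )
    return out


def qc_frame(qc_records: Sequence[QCRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": q.sample_id,
                "ratio_r": q.ratio_r,
                "ratio_r_rounded": None if q.ratio_r is None else round_ratio(q.ratio_r),
                "dispersion_class": q.dispersion_class.value,
                "single_particle": q.single_particle,
                "exclude_from_size_model": q.exclude_from_size_model,
            }
            for q in qc_records
        ]
    )


def screen_redundant_variables(
    table: pd.DataFrame,
    variables: Sequence[str] | None = None,
    rho_threshold: float = 0.7,
) -> pd.DataFrame:
    """Pairwise-Pearson redundancy screen over complete rows.

    Returns one row per variable with its strongest partner, the maximum
    absolute correlation, and a ``dependent`` flag (max |rho| >= threshold).
    Zero-variance variables are an error, named explicitly.
    """
    variables = list(variables) if variables is not None else list(table.columns)
    sub = table[variables].dropna()
    if len(sub) < 3:
        raise ValueError(f"need >= 3 complete rows, have {len(sub)}")
    sds = sub.std(ddof=1)
    dead = sds.index[sds == 0].tolist()
    if dead:
        raise ValueError(f"zero-variance variable(s): {dead}")
    corr = sub.corr(method="pearson")
    rows = []
    for v in variables:
        others = corr[v].drop(v).abs()
        partner = others.idxmax()
        rows.append(
            {
                "variable": v,
                "partner": partner,
                "max_abs_rho": float(others.max()),
                "dependent": bool(others.max() >= rho_threshold),
            }
        )
    return pd.DataFrame(rows)
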