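"""Micellar particle-size model for soap-free emulsion polymerization.

In soap-free emulsion polymerization every growing chain starts from a charged
initiator fragment (here persulfate), and the particle forms from a micelle of
n_poly such chains.  Assuming (i) particle volume proportional to the total
polymer mass n_poly * Mn, (ii) all charges located at the micelle surface, and
(iii) surface potential proportional to surface charge density, the measured
zeta potential scales with n_poly/d^2 and eliminating n_poly leaves a pure
proportionality

    d = k * (-z) * Mn

between the diameter d (nm), the sign-flipped zeta potential -z (mV) and the
number-average molecular weight Mn (kg/mol).  The constant k absorbs polymer
density, packing and the charge-to-potential conversion.  Exponents on (-z)
and Mn are configurable (defaults 1) for variant derivations.

Calibration is least squares through the origin on QC-passing samples only
(aggregated or non-single-particle samples carry a DLS diameter that is not a
particle diameter), with the in-sample root-mean-square prediction error
(RMSPE) reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import ParticleRecord
from .qc import QCRecord

__all__ = ["SizeModelFit", "predict_diameter", "calibrate_k", "rmspe"]


@dataclass
class SizeModelFit:
    """Result of calibrating d = k * (-z)^a * Mn^b.

    ``k`` carries units nm * mV^-a * (kg/mol)^-b; ``rmspe`` is in nm and is an
    in-sample error over the ``n_used`` samples that passed QC;
    ``subset_fraction`` is n_used over the number of samples with complete
    (-z, Mn, d) data.
    """

    k: float
    rmspe: float
    n_used: int
    subset_fraction: float
    exp_z: float = 1.0
    exp_mn: float = 1.0


def predict_diameter(minus_z, mn, k, exp_z: float = 1.0, exp_mn: float = 1.0):
    """Predicted diameter d = k * (-z)^exp_z * Mn^exp_mn, elementwise.

    All inputs must be strictly positive (the model is only meaningful for
    anionic latexes expressed through -z > 0).
    """
    minus_z = np.asarray(minus_z, dtype=float)
    mn = np.asarray(mn, dtype=float)
    if k <= 0:
        raise ValueError(f"k must be > 0, got {k}")
    if np.any(minus_z <= 0):
        raise ValueError("minus_z must be > 0")
    if np.any(mn <= 0):
        raise ValueError("mn must be > 0")
    d = k * minus_z**exp_z * mn**exp_mn
    return float(d) if d.ndim == 0 else d


def rmspe(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Root-mean-square error of prediction, in the units of the inputs."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size == 0:
        raise ValueError(
            f"observed and predicted must have equal nonzero length, "
            f"got {obs.shape} and {pred.shape}"
        )
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def calibrate_k(
    records: Iterable[ParticleRecord],
    qc: Iterable[QCRecord] | None = None,
    exp_z: float = 1.0,
    exp_mn: float = 1.0,
) -> SizeModelFit:
    """Least-squares calibration of k through the origin on QC-passing samples.

    Minimizes sum_i (d_i - k * w_i)^2 with w_i = (-z_i)^exp_z * Mn_i^exp_mn,
    whose closed-form solution is k = sum(d*w)/sum(w*w).  Samples flagged
    ``exclude_from_size_model`` by QC are dropped; when ``qc`` is None all
    complete records are used.
    """
    records = list(records)
    excluded = set()
    if qc is not None:
        excluded = {q.sample_id for q in qc if q.exclude_from_size_model}
    complete = [r for r in records if r.minus_z > 0 and r.mn > 0 and r.d_dls > 0]
    used = [r for r in complete if r.sample_id not in excluded]
    if len(used) < 2:
        raise ValueError(
            f"need >= 2 non-excluded complete records to calibrate, have {len(used)}"
        )
    d = np.array([r.d_dls for r in used])
    w = np.array([r.minus_z**exp_z * r.mn**exp_mn for r in used])
    k = float(np.dot(d, w) / np.dot(w, w))
    err = rmspe(d, k * w)
    return SizeModelFit(
        k=k,
        rmspe=err,
        n_used=len(used),
        subset_fraction=len(used) / len(complete),
        exp_z=exp_z,
        exp_mn=exp_mn,
    )
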