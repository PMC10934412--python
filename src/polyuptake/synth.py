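"""Synthetic styrene/MMA particle libraries with the statistical structure the
downstream analysis assumes.

The generator emulates a 48-member soap-free emulsion copolymerization
library: a full factorial of 5 Sty feed ratios x up to 5 concentration
factors x labelled/nonlabelled, minus two configured gaps.  Built-in trends:

* styrene enrichment in the copolymer — an ideal-copolymerization
  (Mayo–Lewis-shaped, r1*r2 = 1) curve with a single preference ratio,
  calibrated so that a 50 mol % Sty feed yields ~70 mol % Sty in the polymer,
  pinned exactly at the homopolymer endpoints;
* Mn increasing with monomer concentration and decreasing with Sty feed;
* zeta potential negative, with magnitude increasing with concentration;
* true diameters from the micellar forward model d = k_true * (-z) * Mn,
  observed as a 50 nm-rounded SEM diameter and a lognormal-noise DLS
  diameter, occasionally inflated by a DLS aggregation event (factor drawn
  uniformly from 1.5–5, the range seen in real aggregated ratios);
* PdI coupled to the aggregation inflation;
* cellular uptake following U_P = u_S log10(p_tilde) + u_L with
  composition-dependent (u_S, u_L): high and weakly x-dependent for
  phagocytic RAW cells, lower and strongly x-dependent for HEK cells.

Every stochastic draw descends from one integer seed through a fixed
``numpy.random.SeedSequence`` spawn-key scheme (physicochemistry = key 0,
uptake = key 1), so identical parameters give byte-identical tables.  A
row-aligned truth table (latent diameters, uptake parameters, aggregation
flags) is emitted alongside each observation table for parameter-recovery
tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import CONC_AT_UNIT_FACTOR, DesignPoint, ParticleRecord, UptakeMeasurement
from .uptake import correct_load

__all__ = [
    "CellUptakeParams",
    "SynthParams",
    "generate_design",
    "simulate_physicochem",
    "simulate_uptake",
    "simulate_library",
    "DEFAULT_FEEDS",
    "DEFAULT_FACTORS",
    "DEFAULT_DROP",
    "DEFAULT_LOADS",
]

DEFAULT_FEEDS = (0.0, 25.0, 50.0, 75.0, 100.0)
DEFAULT_FACTORS = (0.2, 0.4, 0.6, 0.8, 1.0)
#: Two grid gaps bringing the 5 x 5 x 2 factorial to the 48-member library.
DEFAULT_DROP = ("Sty0MMA1.0N", "Sty0MMA1.0F")
#: Particle loads (ug/mL): onset of considerable uptake, intermediate point,
#: beginning saturation.
DEFAULT_LOADS = (8.0, 80.0, 160.0)


@dataclass(frozen=True)
class CellUptakeParams:
    """Linear maps x (mol % Sty) -> (u_S, u_L) for one cell line, plus noise."""

    slope_base: float
    slope_per_x: float
    level_base: float
    level_per_x: float
    noise_sd: float

    def true_params(self, x: float) -> tuple[float, float]:
        return (
            self.slope_base + self.slope_per_x * x,
            self.level_base + self.level_per_x * x,
        )


def _default_uptake_params() -> dict[str, CellUptakeParams]:
    return {
        # phagocytic: high uptake, scavenger-receptor driven, weak x-dependence
        "RAW": CellUptakeParams(30.0, 0.03, 15.0, 0.03, 3.0),
        # nonphagocytic: endocytosis, strongly increasing with Sty content
        "HEK": CellUptakeParams(10.0, 0.15, 0.0, 0.15, 3.0),
    }


@dataclass(frozen=True)
class SynthParams:
    """All knobs of the synthetic library; defaults are the study conditions.

    Units: concentrations mol/L, Mn kg/mol, diameters nm, zeta mV, solid
    contents ug/mL, U_P %.  ``k_true`` is the micellar proportionality
    constant in nm/(mV * kg/mol); ``n_poly_scale`` scales the latent
    chains-per-particle count reported in the truth table.
    """

    enrichment_ratio: float = 7.0 / 3.0  # feed 50 -> x 70
    mn_base: float = 400.0
    mn_slope_conc: float = 150.0  # kg/mol per mol/L
    mn_slope_feed: float = 2.0  # kg/mol per mol % Sty in the feed
    mn_noise_sd: float = 25.0
    zeta_base: float = 20.0  # -z (mV) extrapolated to c = 0
    zeta_slope_conc: float = 10.0  # mV per mol/L
    zeta_noise_sd: float = 1.5
    k_true: float = 0.022  # nm per (mV * kg/mol)
    n_poly_scale: float = 1.0
    x_noise_sd: float = 2.0  # mol %, the characteristic NIR composition error
    d_noise_sd: float = 0.08  # lognormal sigma on the DLS diameter
    aggregate_prob: float = 0.15
    aggregate_factor_range: tuple[float, float] = (1.5, 5.0)
    sem_round_nm: float = 50.0
    pdi_base: float = 0.08
    pdi_noise_sd: float = 0.02
    pdi_aggregation_gain: float = 0.15  # PdI per unit DLS inflation above 1
    solid_per_conc: float = 1.0e5  # ug/mL theoretical solid per mol/L monomer
    solid_recovery_range: tuple[float, float] = (0.75, 1.0)  # dialysis losses
    uptake_params: dict[str, CellUptakeParams] = field(
        default_factory=_default_uptake_params
    )
    conc_at_unit_factor: float = CONC_AT_UNIT_FACTOR
    seed: int = 0

    def __post_init__(self) -> None:
        # accept lists from YAML configs for the range fields
        for name in ("aggregate_factor_range", "solid_recovery_range"):
            object.__setattr__(self, name, tuple(getattr(self, name)))
        for name in ("mn_noise_sd", "zeta_noise_sd", "x_noise_sd", "d_noise_sd",
                     "pdi_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.aggregate_prob <= 1:
            raise ValueError("aggregate_prob must be in [0, 1]")
        if self.k_true <= 0:
            raise ValueError("k_true must be > 0")

    def noiseless(self) -> "SynthParams":
        """Copy with every noise source, rounding and random gap switched off."""
        return dataclasses.replace(
            self,
            mn_noise_sd=0.0,
            zeta_noise_sd=0.0,
            x_noise_sd=0.0,
            d_noise_sd=0.0,
            pdi_noise_sd=0.0,
            aggregate_prob=0.0,
            sem_round_nm=0.0,
            solid_recovery_range=(1.0, 1.0),
            uptake_params={
                k: dataclasses.replace(v, noise_sd=0.0)
                for k, v in self.uptake_params.items()
            },
        )

    def rng(self, stream: int) -> np.random.Generator:
        """Named child stream of the master seed (0 = physicochem, 1 = uptake)."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(stream,))
        )


def generate_design(
    feeds: Sequence[float] = DEFAULT_FEEDS,
    factors: Sequence[float] = DEFAULT_FACTORS,
    labels: str = "both",
    drop: Sequence[str] = DEFAULT_DROP,
    conc_at_unit_factor: float = CONC_AT_UNIT_FACTOR,
) -> list[DesignPoint]:
    """Full factorial design grid, minus the configured gap list.

    ``labels`` is ``"both"``, ``"N"`` or ``"F"``.  Deterministic: points are
    ordered by (feed, factor, label).
    """
    if not feeds or not factors:
        raise ValueError("feeds and factors must be nonempty")
    if labels not in ("both", "N", "F"):
        raise ValueError(f"labels must be 'both', 'N' or 'F', got {labels!r}")
    labelled_options = [False, True] if labels == "both" else [labels == "F"]
    drop = set(drop)
    points = []
    for feed in sorted(feeds):
        for factor in sorted(factors):
            for lab in labelled_options:
                dp = DesignPoint(
                    sty_feed=float(feed),
                    conc_factor=float(factor),
                    labeled=lab,
                    monomer_conc=float(factor) * conc_at_unit_factor,
                )
                if dp.sample_id not in drop:
                    points.append(dp)
    return points


def _enrichment_x(feed: float, ratio: float) -> float:
    """Ideal-copolymerization composition curve, endpoints pinned exactly."""
    f = feed / 100.0
    if f <= 0.0:
        return 0.0
    if f >= 1.0:
        return 100.0
    return 100.0 * ratio * f / (ratio * f + (1.0 - f))


def simulate_physicochem(
    designs: Iterable[DesignPoint], params: SynthParams
) -> tuple[list[ParticleRecord], pd.DataFrame]:
    """Simulate physicochemical observations plus a row-aligned truth table."""
    designs = list(designs)
    rng = params.rng(0)
    records: list[ParticleRecord] = []
    truth_rows = []
    for dp in designs:
        c = dp.monomer_conc
        x_true = _enrichment_x(dp.sty_feed, params.enrichment_ratio)
        mn_true = (
            params.mn_base
            + params.mn_slope_conc * c
            - params.mn_slope_feed * dp.sty_feed
        )
        if mn_true <= 0:
            raise ValueError(
                f"mn trend parameters give non-positive Mn at {dp.sample_id}"
            )
        minus_z_true = params.zeta_base + params.zeta_slope_conc * c
        d_true = params.k_true * minus_z_true * mn_true
        # surface-charge bookkeeping: chains per particle from charge density
        n_poly = params.n_poly_scale * minus_z_true * d_true**2

        if dp.sty_feed in (0.0, 100.0):
            x_obs = x_true  # homopolymer composition is known exactly
        else:
            x_obs = float(
                np.clip(x_true + rng.normal(0.0, params.x_noise_sd), 0.0, 100.0)
            )
        mn_obs = float(max(mn_true + rng.normal(0.0, params.mn_noise_sd), 1.0))
        minus_z_obs = float(
            max(minus_z_true + rng.normal(0.0, params.zeta_noise_sd), 0.1)
        )
        aggregated = bool(rng.random() < params.aggregate_prob)
        inflation = (
            float(rng.uniform(*params.aggregate_factor_range)) if aggregated else 1.0
        )
        d_dls = float(
            d_true * np.exp(rng.normal(0.0, params.d_noise_sd)) * inflation
        )
        if params.sem_round_nm > 0:
            d_sem = float(
                max(round(d_true / params.sem_round_nm) * params.sem_round_nm,
                    params.sem_round_nm)
            )
        else:
            d_sem = d_true
        pdi = float(
            max(
                params.pdi_base
                + params.pdi_aggregation_gain * (inflation - 1.0)
                + rng.normal(0.0, params.pdi_noise_sd),
                0.0,
            )
        )
        solid_theoretical = params.solid_per_conc * c
        recovery = float(rng.uniform(*params.solid_recovery_range))
        solid_measured = solid_theoretical * recovery

        records.append(
            ParticleRecord(
                sample_id=dp.sample_id,
                design=dp,
                x_sty=x_obs,
                mn=mn_obs,
                d_dls=d_dls,
                pdi=pdi,
                zeta=-minus_z_obs,
                d_sem=d_sem,
                solid_theoretical=solid_theoretical,
                solid_measured=solid_measured,
            )
        )
        truth_rows.append(
            {
                "sample_id": dp.sample_id,
                "x_true": x_true,
                "mn_true": mn_true,
                "minus_z_true": minus_z_true,
                "d_true": d_true,
                "n_poly": n_poly,
                "aggregated": aggregated,
                "dls_inflation": inflation,
                "solid_recovery": recovery,
            }
        )
    return records, pd.DataFrame(truth_rows)


def simulate_uptake(
    records: Iterable[ParticleRecord],
    params: SynthParams,
    loads: Sequence[float] = DEFAULT_LOADS,
    replicates: int = 1,
    labeled_only: bool = True,
) -> tuple[list[UptakeMeasurement], pd.DataFrame]:
    """Simulate per-load uptake measurements plus a truth table.

    Only fluorescence-labelled particles can be followed by flow cytometry, so
    nonlabelled records are skipped unless ``labeled_only`` is False.
    ``replicates`` > 1 emits replicate rows per (sample, cell, load),
    mirroring replicated flow-cytometry measurements.
    """
    records = list(records)
    loads = [float(p) for p in loads]
    if any(p <= 0 for p in loads):
        raise ValueError("loads must be > 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = params.rng(1)
    measurements: list[UptakeMeasurement] = []
    truth_rows = []
    for rec in records:
        if labeled_only and not rec.design.labeled:
            continue
        for cell_line in sorted(params.uptake_params):
            cp = params.uptake_params[cell_line]
            u_s, u_l = cp.true_params(rec.x_sty)
            truth_rows.append(
                {
                    "sample_id": rec.sample_id,
                    "cell_line": cell_line,
                    "u_s_true": u_s,
                    "u_l_true": u_l,
                }
            )
            for p in loads:
                p_tilde = correct_load(
                    p, rec.solid_theoretical, rec.solid_measured
                )
                for _ in range(replicates):
                    u_p = u_s * np.log10(p_tilde) + u_l
                    u_p = float(np.clip(u_p + rng.normal(0.0, cp.noise_sd), 0.0, 100.0))
                    measurements.append(
                        UptakeMeasurement(
                            sample_id=rec.sample_id,
                            cell_line=cell_line,
                            load_p=p,
                            positive_pct=u_p,
                            load_corrected=p_tilde,
                        )
                    )
    return measurements, pd.DataFrame(truth_rows)


def simulate_library(
    params: SynthParams,
    feeds: Sequence[float] = DEFAULT_FEEDS,
    factors: Sequence[float] = DEFAULT_FACTORS,
    labels: str = "both",
    drop: Sequence[str] = DEFAULT_DROP,
    loads: Sequence[float] = DEFAULT_LOADS,
    replicates: int = 1,
):
    """Convenience wrapper: design grid -> records, uptake, both truth tables."""
    designs = generate_design(
        feeds, factors, labels, drop, params.conc_at_unit_factor
    )
    records, truth_phys = simulate_physicochem(designs, params)
    measurements, truth_uptake = simulate_uptake(
        records, params, loads, replicates
    )
    return records, measurements, truth_phys, truth_uptake
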