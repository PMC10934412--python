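"""End-to-end analysis pipeline: QC -> size model -> PCA/MLR -> uptake fits ->
uptake PCA/MLR, from a single config, with reproducible CSV/text artifacts.

Artifacts contain no timestamps, so a re-run with the same config and seed is
byte-identical.  Every sample excluded at any stage is recorded once in
``exclusions.csv`` with a machine-readable reason code (``aggregate``,
``low-solid-content``, ``low-R2``, ``missing-data``).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from . import io as puio
from . import multivariate as mv
from . import qc as puqc
from . import uptake as puuptake
from .micelle import SizeModelFit, calibrate_k
from .synth import (
    DEFAULT_DROP,
    DEFAULT_FACTORS,
    DEFAULT_FEEDS,
    DEFAULT_LOADS,
    CellUptakeParams,
    SynthParams,
    simulate_library,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "default_config"]

#: Variables of the physicochemical PCA (monomer concentration, copolymer
#: composition, molecular weight, DLS diameter, sign-flipped zeta potential).
PHYSCHEM_PCA_VARS = ("c", "x", "Mn", "d", "-z")
#: Variables of the uptake PCA.
UPTAKE_PCA_VARS = ("x", "Mn^2", "d", "-z", "U_P(RAW)", "U_P(HEK)")


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_pipeline`.

    Exactly one of (``library_path``) or (``synthetic``) must be set; an
    uptake table may accompany a library table.  Thresholds default to the
    values used throughout the analysis: single particles below 800 nm (DLS),
    aggregation at r > 1.2, uptake-series exclusion at R^2 < 0.80, U_P
    reported at a 100 ug/mL load.
    """

    library_path: str | None = None
    uptake_path: str | None = None
    synthetic: SynthParams | None = None
    feeds: Sequence[float] = DEFAULT_FEEDS
    factors: Sequence[float] = DEFAULT_FACTORS
    labels: str = "both"
    drop: Sequence[str] = DEFAULT_DROP
    loads: Sequence[float] = DEFAULT_LOADS
    replicates: int = 1
    single_particle_threshold_nm: float = puqc.SINGLE_PARTICLE_THRESHOLD_NM
    rho_threshold: float = 0.7
    exp_z: float = 1.0
    exp_mn: float = 1.0
    r2_threshold: float = puuptake.R2_EXCLUSION_THRESHOLD
    reference_load: float = puuptake.REFERENCE_LOAD
    min_solid_recovery: float = 0.05
    mlr_physchem_predictors: Sequence[str] = ("x", "-z", "Mn")
    mlr_uptake_predictors: Sequence[str] = ("x", "Mn^2", "d", "-z")
    mlr_uptake_response: str = "U_P(HEK)"

    def __post_init__(self) -> None:
        if (self.library_path is None) == (self.synthetic is None):
            raise ValueError(
                "config error: exactly one of library_path or synthetic "
                "parameters must be set"
            )
        if not 0 < self.r2_threshold <= 1:
            raise ValueError("r2_threshold must be in (0, 1]")
        if self.single_particle_threshold_nm <= 0:
            raise ValueError("single_particle_threshold_nm must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        raw = dict(raw)
        synth = raw.pop("synthetic", None)
        if synth is not None:
            uptake = synth.pop("uptake_params", None)
            if uptake is not None:
                synth["uptake_params"] = {
                    cell: CellUptakeParams(**p) for cell, p in uptake.items()
                }
            synth = SynthParams(**synth)
        return cls(synthetic=synth, **raw)


def default_config() -> dict[str, Any]:
    """All pipeline and generator defaults as one nested plain dict."""
    cfg = {
        f.name: getattr(PipelineConfig, f.name, None)
        for f in dataclasses.fields(PipelineConfig)
        if f.name not in ("library_path", "uptake_path", "synthetic")
    }
    cfg = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in cfg.items()
        if not callable(v)
    }
    synth = dataclasses.asdict(SynthParams())
    synth["uptake_params"] = {
        cell: dataclasses.asdict(p)
        for cell, p in SynthParams().uptake_params.items()
    }
    cfg["synthetic"] = synth
    return cfg


@dataclass
class PipelineResult:
    records: list
    measurements: list
    qc_records: list
    redundancy: pd.DataFrame
    size_fit: SizeModelFit | None
    pca_physchem: mv.PCAResult | None
    mlr_physchem: mv.MLRResult | None
    uptake_fits: list
    uptake_summaries: dict[str, dict[str, float]]
    feature_table: pd.DataFrame | None
    pca_uptake: mv.PCAResult | None
    mlr_uptake: mv.MLRResult | None
    exclusions: pd.DataFrame
    truth_physchem: pd.DataFrame | None = None
    truth_uptake: pd.DataFrame | None = None
    pca_physchem_index: pd.Index | None = None


def _physchem_frame(records) -> pd.DataFrame:
    rows = {
        "sample_id": [r.sample_id for r in records],
        "c": [r.design.monomer_conc for r in records],
        "x": [r.x_sty for r in records],
        "Mn": [r.mn for r in records],
        "d": [r.d_dls for r in records],
        "-z": [mv.transform_zeta(r.zeta) for r in records],
        "PdI": [r.pdi for r in records],
    }
    return pd.DataFrame(rows).set_index("sample_id")


def run_pipeline(config: PipelineConfig, outdir=None) -> PipelineResult:
    """Run all stages in order; write artifacts to ``outdir`` when given."""
    exclusions: list[dict[str, str]] = []
    truth_phys = truth_upt = None

    # --- stage 1: inputs -------------------------------------------------
    if config.synthetic is not None:
        records, measurements, truth_phys, truth_upt = simulate_library(
            config.synthetic,
            feeds=config.feeds,
            factors=config.factors,
            labels=config.labels,
            drop=config.drop,
            loads=config.loads,
            replicates=config.replicates,
        )
    else:
        records = puio.read_library_table(config.library_path)
        measurements = (
            puio.read_uptake_table(config.uptake_path)
            if config.uptake_path is not None
            else []
        )
    logger.info("pipeline: %d library members, %d uptake measurements",
                len(records), len(measurements))

    # --- stage 2: size QC ------------------------------------------------
    qc_records = puqc.flag_single_particles(
        records, config.single_particle_threshold_nm
    )
    for q in qc_records:
        if q.exclude_from_size_model:
            exclusions.append(
                {"sample_id": q.sample_id, "stage": "size_qc", "reason": "aggregate"}
            )
    phys = _physchem_frame(records)
    redundancy = puqc.screen_redundant_variables(
        phys, list(PHYSCHEM_PCA_VARS) + ["PdI"], config.rho_threshold
    )

    # --- stage 3: micellar size model ------------------------------------
    size_fit = None
    try:
        size_fit = calibrate_k(records, qc_records, config.exp_z, config.exp_mn)
    except ValueError as exc:
        logger.warning("size model skipped: %s", exc)

    # --- stage 4: physicochemical PCA + MLR ------------------------------
    # QC-excluded samples carry a DLS diameter that is not a particle
    # diameter (aggregates), so they stay out of the diameter analyses
    pca_phys = mlr_phys = None
    pca_phys_index = None
    qc_pass = [q.sample_id for q in qc_records if not q.exclude_from_size_model]
    phys_pass = phys.loc[[s for s in phys.index if s in set(qc_pass)]]
    if len(phys_pass) >= 3:
        std, means, sds = mv.standardize(phys_pass, PHYSCHEM_PCA_VARS)
        pca_phys = mv.pca(std)
        pca_phys.centering_means = means
        pca_phys.scaling_sds = sds
        pca_phys_index = std.index
        mlr_phys = mv.mlr_fit(phys_pass, config.mlr_physchem_predictors, "d")

    # --- stage 5: uptake fits --------------------------------------------
    usable = []
    low_solid = set()
    for r in records:
        if (
            r.solid_theoretical is not None
            and r.solid_measured is not None
            and r.solid_measured / r.solid_theoretical < config.min_solid_recovery
        ):
            low_solid.add(r.sample_id)
            exclusions.append(
                {
                    "sample_id": r.sample_id,
                    "stage": "uptake",
                    "reason": "low-solid-content",
                }
            )
    fits = []
    summaries: dict[str, dict[str, float]] = {}
    feature = pca_upt = mlr_upt = None
    if measurements:
        usable = [m for m in measurements if m.sample_id not in low_solid]
        fits = puuptake.fit_all_uptake(
            usable,
            records,
            r2_threshold=config.r2_threshold,
            reference_load=config.reference_load,
        )
        for f in fits:
            if f.excluded:
                exclusions.append(
                    {
                        "sample_id": f.sample_id,
                        "stage": f"uptake/{f.cell_line}",
                        "reason": "low-R2",
                    }
                )
        for cell in sorted({f.cell_line for f in fits}):
            try:
                summaries[cell] = puuptake.summarize_uptake(fits, cell)
            except ValueError as exc:
                logger.warning("no %s uptake summary: %s", cell, exc)

        # --- stage 6: uptake PCA + MLR -----------------------------------
        feature_full = puuptake.uptake_feature_table(fits, records)
        feature = feature_full.dropna()
        for sid in feature_full.index.difference(feature.index):
            exclusions.append(
                {"sample_id": sid, "stage": "uptake_mva", "reason": "missing-data"}
            )
        if len(feature) >= len(UPTAKE_PCA_VARS):
            std_u, means_u, sds_u = mv.standardize(feature, UPTAKE_PCA_VARS)
            pca_upt = mv.pca(std_u)
            pca_upt.centering_means = means_u
            pca_upt.scaling_sds = sds_u
            mlr_upt = mv.mlr_fit(
                feature, config.mlr_uptake_predictors, config.mlr_uptake_response
            )
        else:
            logger.warning(
                "uptake multivariate stage skipped: only %d complete samples",
                len(feature),
            )

    result = PipelineResult(
        records=records,
        measurements=measurements,
        qc_records=qc_records,
        redundancy=redundancy,
        size_fit=size_fit,
        pca_physchem=pca_phys,
        mlr_physchem=mlr_phys,
        uptake_fits=fits,
        uptake_summaries=summaries,
        feature_table=feature,
        pca_uptake=pca_upt,
        mlr_uptake=mlr_upt,
        exclusions=pd.DataFrame(
            exclusions, columns=["sample_id", "stage", "reason"]
        ),
        truth_physchem=truth_phys,
        truth_uptake=truth_upt,
        pca_physchem_index=pca_phys_index,
    )
    if outdir is not None:
        _write_bundle(result, Path(outdir))
    return result


def _mlr_frame(fit: mv.MLRResult) -> pd.DataFrame:
    rows = [{"term": "intercept", "coefficient": fit.intercept, "impact": None}]
    for name, beta in fit.coefficients.items():
        rows.append(
            {"term": name, "coefficient": beta, "impact": fit.impact[name]}
        )
    return pd.DataFrame(rows)


def _write_bundle(res: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    puio.write_library_table(res.records, outdir / "library.csv")
    if res.measurements:
        puio.write_uptake_table(res.measurements, outdir / "uptake.csv")
    if res.truth_physchem is not None:
        res.truth_physchem.to_csv(outdir / "library_truth.csv", index=False)
    if res.truth_uptake is not None:
        res.truth_uptake.to_csv(outdir / "uptake_truth.csv", index=False)
    puqc.qc_frame(res.qc_records).to_csv(outdir / "qc.csv", index=False)
    res.redundancy.to_csv(outdir / "redundancy.csv", index=False)
    res.exclusions.to_csv(outdir / "exclusions.csv", index=False)
    if res.pca_physchem is not None:
        res.pca_physchem.loadings_frame().to_csv(outdir / "pca_physchem_loadings.csv")
        res.pca_physchem.scores_frame(index=res.pca_physchem_index).to_csv(
            outdir / "pca_physchem_scores.csv"
        )
    if res.mlr_physchem is not None:
        _mlr_frame(res.mlr_physchem).to_csv(outdir / "mlr_physchem.csv", index=False)
    if res.uptake_fits:
        puuptake.fits_to_frame(res.uptake_fits).to_csv(
            outdir / "uptake_fits.csv", index=False
        )
    if res.feature_table is not None:
        res.feature_table.to_csv(outdir / "uptake_features.csv")
    if res.pca_uptake is not None:
        res.pca_uptake.loadings_frame().to_csv(outdir / "pca_uptake_loadings.csv")
        res.pca_uptake.scores_frame(index=res.feature_table.index).to_csv(
            outdir / "pca_uptake_scores.csv"
        )
    if res.mlr_uptake is not None:
        _mlr_frame(res.mlr_uptake).to_csv(outdir / "mlr_uptake.csv", index=False)
    (outdir / "report.txt").write_text(render_report(res))


def render_report(res: PipelineResult) -> str:
    """Plain-text summary of every stage (deterministic: no timestamps)."""
    lines: list[str] = []
    n_qc_excl = sum(q.exclude_from_size_model for q in res.qc_records)
    lines.append("== particle library pipeline report ==")
    lines.append(f"library members: {len(res.records)}")
    lines.append(
        f"size QC: {n_qc_excl} excluded from size model "
        f"(aggregated or >= single-particle threshold)"
    )
    dep = res.redundancy[res.redundancy["dependent"]]
    for _, row in dep.iterrows():
        lines.append(
            f"redundancy: {row['variable']} dependent on {row['partner']} "
            f"(|rho| = {row['max_abs_rho']:.2f})"
        )
    if res.size_fit is not None:
        f = res.size_fit
        lines.append(
            f"size model d = k*(-z)^{f.exp_z:g}*Mn^{f.exp_mn:g}: "
            f"k = {f.k:.6g} nm/(mV*kg/mol), RMSPE = {f.rmspe:.4g} nm, "
            f"n = {f.n_used} ({100 * f.subset_fraction:.0f}% of complete data)"
        )
    if res.pca_physchem is not None:
        ev = res.pca_physchem.explained_fraction
        lines.append(
            "physicochemical PCA explained variance: "
            + ", ".join(f"PC{i + 1} {100 * v:.1f}%" for i, v in enumerate(ev))
        )
        lines.append(res.pca_physchem.loadings_frame().round(3).to_string())
    if res.mlr_physchem is not None:
        m = res.mlr_physchem
        lines.append(
            f"physicochemical MLR (d): RMSPE = {m.rmspe:.4g} nm, "
            f"R^2 = {m.r_squared:.4f}, impacts "
            + ", ".join(f"{k} {v:.3f}" for k, v in m.impact.items())
        )
    for cell, s in res.uptake_summaries.items():
        lines.append(
            f"uptake {cell}: U_P(ref) = {s['mean']:.1f} +/- {s['sd']:.1f} % "
            f"(n = {s['n']})"
        )
    if res.pca_uptake is not None:
        ev = res.pca_uptake.explained_fraction
        lines.append(
            "uptake PCA explained variance: "
            + ", ".join(f"PC{i + 1} {100 * v:.1f}%" for i, v in enumerate(ev))
        )
        lines.append(res.pca_uptake.loadings_frame().round(3).to_string())
    if res.mlr_uptake is not None:
        m = res.mlr_uptake
        lines.append(
            f"uptake MLR ({', '.join(m.coefficients)} -> response): "
            f"RMSPE = {m.rmspe:.4g} %, R^2 = {m.r_squared:.4f}, impacts "
            + ", ".join(f"{k} {v:.3f}" for k, v in m.impact.items())
        )
    lines.append(f"exclusion log entries: {len(res.exclusions)}")
    return "\n".join(lines) + "\n"
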