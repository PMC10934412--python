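"""Logarithmic uptake model: load correction, fitting, exclusion, summaries."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from polyuptake.io import UptakeMeasurement
from polyuptake.reference_data import reference_uptake_fits, uptake_fit_reference
from polyuptake.uptake import (
    correct_load,
    fit_uptake,
    summarize_uptake,
    uptake_feature_table,
)


def _series(sample, cell, loads, u_p):
    return [
        UptakeMeasurement(sample_id=sample, cell_line=cell, load_p=p,
                          positive_pct=v)
        for p, v in zip(loads, u_p)
    ]


# ------------------------------------------------------------- load correction


def test_correct_load_examples():
    assert correct_load(100.0, 7.0, 7.0, 1.0) == pytest.approx(100.0)
    assert correct_load(100.0, 10.0, 5.0, 1.0) == pytest.approx(50.0)
    assert correct_load(100.0) == pytest.approx(100.0)  # p0 defaults to 1 ug/mL


def test_correct_load_rejects_nonpositive():
    with pytest.raises(ValueError):
        correct_load(-1.0)
    with pytest.raises(ValueError):
        correct_load(100.0, 10.0, -5.0)


# ------------------------------------------------------------------- fitting


def test_fit_recovers_exact_log_linear_data():
    loads = [8.0, 80.0, 160.0]
    u_s, u_l = 20.0, 10.0
    u_p = [u_s * math.log10(p) + u_l for p in loads]
    fit = fit_uptake(_series("Sty50MMA0.8F", "HEK", loads, u_p))
    assert fit.u_s == pytest.approx(u_s, abs=1e-12)
    assert fit.u_l == pytest.approx(u_l, abs=1e-12)
    assert fit.r_squared == pytest.approx(1.0)
    assert not fit.excluded
    assert fit.u_p_ref == pytest.approx(u_s * 2 + u_l, abs=1e-10)


def test_reference_value_above_100_is_capped():
    # exactly log-linear points whose extrapolation at p = 100 exceeds 100 %
    loads = [2.0, 8.0, 32.0]
    u_p = [40 * math.log10(p) + 30 for p in loads]
    fit = fit_uptake(_series("Sty75MMA1.0F", "RAW", loads, u_p))
    assert fit.u_p_ref_raw > 100
    assert fit.u_p_ref == 100.0


def test_flat_noise_series_is_excluded(rng):
    loads = np.repeat([8.0, 80.0, 160.0], 3)
    u_p = np.clip(50 + rng.normal(0, 3, size=9), 0, 100)
    fit = fit_uptake(_series("Sty0MMA0.2F", "HEK", loads, u_p))
    assert fit.excluded
    assert fit.u_p_ref is None


def test_constant_uptake_when_slope_zero():
    loads = [8.0, 80.0, 160.0]
    fit = fit_uptake(_series("Sty0MMA0.2F", "HEK", loads, [42.0, 42.0, 42.0]))
    assert fit.u_s == pytest.approx(0.0, abs=1e-12)
    assert fit.r_squared == pytest.approx(1.0)  # exact flat fit


def test_fit_requires_three_distinct_loads():
    with pytest.raises(ValueError, match="distinct loads"):
        fit_uptake(_series("Sty0MMA0.2F", "HEK", [8, 8, 8], [1, 2, 3]))
    with pytest.raises(ValueError, match="distinct loads"):
        fit_uptake(_series("Sty0MMA0.2F", "HEK", [8, 80], [1, 2]))


def test_fit_rejects_mixed_series():
    ms = _series("Sty0MMA0.2F", "HEK", [8, 80, 160], [1, 2, 3])
    ms += _series("Sty0MMA0.2F", "RAW", [8, 80, 160], [1, 2, 3])
    with pytest.raises(ValueError, match="multiple"):
        fit_uptake(ms)


@given(shift=st.floats(-20, 20), scale=st.floats(0.1, 10))
def test_fit_equivariance(shift, scale):
    """Adding c to U_P shifts u_L by c; scaling loads by a shifts u_L by
    -u_S*log10(a) and leaves u_S unchanged."""
    loads = np.array([8.0, 80.0, 160.0])
    u_p = np.array([30.0, 50.0, 56.0])
    base = fit_uptake(_series("Sty50MMA0.8F", "HEK", loads, u_p))
    shifted = fit_uptake(
        _series("Sty50MMA0.8F", "HEK", loads, np.clip(u_p + shift, 0, 100))
    )
    if np.all((u_p + shift >= 0) & (u_p + shift <= 100)):
        assert shifted.u_s == pytest.approx(base.u_s, abs=1e-9)
        assert shifted.u_l == pytest.approx(base.u_l + shift, abs=1e-9)
    scaled = fit_uptake(_series("Sty50MMA0.8F", "HEK", loads * scale, u_p))
    assert scaled.u_s == pytest.approx(base.u_s, abs=1e-9)
    assert scaled.u_l == pytest.approx(
        base.u_l - base.u_s * math.log10(scale), abs=1e-8
    )


def test_replicate_expected_error():
    loads = np.repeat([8.0, 80.0, 160.0], 2)
    u_p = [30.0, 34.0, 50.0, 54.0, 60.0, 64.0]  # within-load sd = 2*sqrt(2)
    fit = fit_uptake(_series("Sty50MMA0.8F", "HEK", loads, u_p))
    assert fit.expected_error == pytest.approx(2 * math.sqrt(2))
    # no replicates -> no Er
    fit2 = fit_uptake(_series("Sty50MMA0.8F", "HEK", [8, 80, 160], [30, 50, 60]))
    assert fit2.expected_error is None


def test_solid_content_correction_shifts_level():
    loads = [8.0, 80.0, 160.0]
    u_p = [20 * math.log10(p) + 10 for p in loads]
    plain = fit_uptake(_series("Sty50MMA0.8F", "HEK", loads, u_p))
    corrected = fit_uptake(
        _series("Sty50MMA0.8F", "HEK", loads, u_p),
        solid_theoretical=10.0,
        solid_measured=5.0,
    )
    # halving the effective load shifts the intercept, not the slope
    assert corrected.u_s == pytest.approx(plain.u_s, abs=1e-9)
    assert corrected.u_l == pytest.approx(
        plain.u_l + plain.u_s * math.log10(2), abs=1e-9
    )


# ------------------------------------------------------------------ summaries


def test_reference_cohort_summary_raw():
    """The 20 non-excluded published RAW values average 75.4 +/- 12.1 %."""
    fits = reference_uptake_fits()
    s = summarize_uptake(fits, "RAW")
    assert s["n"] == 20
    assert round(s["mean"], 1) == 75.4
    assert round(s["sd"], 1) == 12.1


def test_summary_identical_values_and_oracle(rng):
    fits = reference_uptake_fits()
    vals = [f.u_p_ref for f in fits if f.cell_line == "RAW" and not f.excluded]
    # two-pass oracle
    mean = sum(vals) / len(vals)
    sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (len(vals) - 1))
    s = summarize_uptake(fits, "RAW")
    assert s["mean"] == pytest.approx(mean)
    assert s["sd"] == pytest.approx(sd)


def test_summary_requires_two_values():
    fits = [f for f in reference_uptake_fits() if f.cell_line == "RAW"][:1]
    with pytest.raises(ValueError, match=">= 2"):
        summarize_uptake(fits, "RAW")


def test_excluded_series_count_matches_reference():
    ref = uptake_fit_reference()
    assert int(ref["u_p_ref"].isna().sum()) == 5  # 1 RAW + 4 HEK series


# -------------------------------------------------------------- feature table


def test_feature_table_from_synthetic_library(default_library):
    records, measurements, _, _ = default_library
    from polyuptake.uptake import fit_all_uptake

    fits = fit_all_uptake(measurements, records)
    table = uptake_feature_table(fits, records)
    labeled = [r for r in records if r.design.labeled]
    n_excluded_samples = len(
        {f.sample_id for f in fits if f.excluded}
    )
    assert len(table) >= len(labeled) - n_excluded_samples - 1
    by_id = {r.sample_id: r for r in records}
    for sid, row in table.iterrows():
        assert row["Mn^2"] == pytest.approx(by_id[sid].mn ** 2)
        assert row["-z"] == pytest.approx(-by_id[sid].zeta)


def test_feature_table_rejects_disjoint_ids(default_library):
    records, measurements, _, _ = default_library
    from polyuptake.uptake import fit_all_uptake

    fits = fit_all_uptake(measurements, records)
    strangers = [r for r in records if not r.design.labeled]
    renamed = []
    import dataclasses

    for r in strangers:
        renamed.append(dataclasses.replace(r, sample_id=r.sample_id + "_other"))
    with pytest.raises(ValueError, match="overlap"):
        uptake_feature_table(fits, renamed)
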