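"""Published reference tables for the 48-member styrene/MMA particle library.

Two small printed tables from the library's published characterization are
bundled for validation and worked examples:

* the DLS/SEM diameter comparison (20 samples measured by both methods, with
  the printed 1-decimal ratio r and its footnote class: ``aggregated`` for
  r > 1.2, ``over_approximated`` for r < 0.8), and
* the per-sample uptake fits for RAW264.7 and HEK cells (u_S, u_L, the
  reported U_P at a 100 ug/mL particle load, and the replicate-derived
  expected error Er), where series with model correlation R^2 < 0.8 carry no
  U_P and one calculative U_P above 100 % was reported capped at 100 %.

These are inputs (printed values), not package outputs; the test suite checks
that recomputing r and the cohort summaries from them reproduces the printed
numbers.
"""

from __future__ import annotations

import io

import pandas as pd

from .uptake import UptakeFit

__all__ = [
    "dls_sem_reference",
    "uptake_fit_reference",
    "reference_uptake_fits",
]

# d(SEM) and d(DLS) in nm; r_printed is the published 1-decimal ratio;
# printed_class from the table footnotes (empty = no footnote = consistent).
_DLS_SEM_CSV = """\
sample_id,d_sem_nm,d_dls_nm,r_printed,printed_class
Sty0MMA0.8N,500,1469,2.9,aggregated
Sty0MMA0.8F,400,1800,4.5,aggregated
Sty0MMA0.2N,300,1509,5.0,aggregated
Sty0MMA0.2F,500,401,0.8,
Sty25MMA1.0N,500,555,1.1,
Sty25MMA1.0F,800,460,0.6,over_approximated
Sty25MMA0.2N,300,358,1.2,
Sty25MMA0.2F,,238,,
Sty50MMA1.0N,600,706,1.2,
Sty50MMA1.0F,800,490,0.6,over_approximated
Sty50MMA0.2N,200,189,0.9,
Sty50MMA0.2F,250,259,1.0,
Sty75MMA1.0N,400,398,1.0,
Sty75MMA1.0F,500,407,0.8,
Sty75MMA0.2N,400,409,1.0,
Sty75MMA0.2F,350,237,0.7,over_approximated
Sty100MMA1.0N,600,561,0.9,
Sty100MMA1.0F,700,420,0.6,over_approximated
Sty100MMA0.2N,500,505,1.0,
Sty100MMA0.2F,500,308,0.6,over_approximated
"""

# Long format; u_p_ref empty where the series was excluded (R^2 < 0.8);
# u_p_capped marks the one calculative value > 100 % reported as 100.
_UPTAKE_FIT_CSV = """\
sample_id,cell_line,u_s,u_l,u_p_ref,er,u_p_capped
Sty0MMA0.8F,RAW,51,41,60,4,False
Sty0MMA0.6F,RAW,57,45,69,7,False
Sty0MMA0.4F,RAW,66,50,82,10,False
Sty0MMA0.2F,RAW,67,64,71,10,False
Sty25MMA1.0F,RAW,59,46,71,9,False
Sty25MMA0.8F,RAW,64,53,75,8,False
Sty25MMA0.6F,RAW,70,52,89,10,False
Sty25MMA0.4F,RAW,58,46,71,9,False
Sty50MMA1.0F,RAW,71,69,72,8,False
Sty50MMA0.8F,RAW,74,74,75,8,False
Sty50MMA0.6F,RAW,54,58,50,8,False
Sty50MMA0.4F,RAW,65,70,59,7,False
Sty75MMA1.0F,RAW,74,56,92,5,False
Sty75MMA0.8F,RAW,72,65,79,5,False
Sty75MMA0.6F,RAW,73,72,73,3,False
Sty75MMA0.4F,RAW,71,74,69,6,False
Sty75MMA0.2F,RAW,73,72,74,12,False
Sty100MMA1.0F,RAW,0.88,0.12,,,False
Sty100MMA0.8F,RAW,65,38,92,3,False
Sty100MMA0.6F,RAW,69,26,100,8,True
Sty100MMA0.2F,RAW,67,49,85,9,False
Sty0MMA0.8F,HEK,24,18,29,11,False
Sty0MMA0.6F,HEK,43,37,48,10,False
Sty0MMA0.4F,HEK,40,32,47,7,False
Sty0MMA0.2F,HEK,27,28,26,10,False
Sty25MMA1.0F,HEK,35,30,40,11,False
Sty25MMA0.8F,HEK,58,54,61,8,False
Sty25MMA0.6F,HEK,45,36,54,8,False
Sty25MMA0.4F,HEK,43,35,51,10,False
Sty50MMA1.0F,HEK,67,74,61,8,False
Sty50MMA0.8F,HEK,68,72,64,7,False
Sty50MMA0.6F,HEK,24,27,,16,False
Sty50MMA0.4F,HEK,15,17,,12,False
Sty75MMA1.0F,HEK,73,60,86,7,False
Sty75MMA0.8F,HEK,74,73,76,8,False
Sty75MMA0.6F,HEK,74,82,65,8,False
Sty75MMA0.4F,HEK,71,85,57,7,False
Sty75MMA0.2F,HEK,33,39,,7,False
Sty100MMA1.0F,HEK,13,3.1,,9,False
Sty100MMA0.8F,HEK,76,64,89,5,False
Sty100MMA0.6F,HEK,53,24,81,8,False
Sty100MMA0.2F,HEK,67,68,65,6,False
"""


def dls_sem_reference() -> pd.DataFrame:
    """The published DLS/SEM diameter comparison (one row per sample)."""
    df = pd.read_csv(io.StringIO(_DLS_SEM_CSV))
    df["printed_class"] = df["printed_class"].fillna("consistent")
    df.loc[df["d_sem_nm"].isna(), "printed_class"] = "unknown"
    return df


def uptake_fit_reference() -> pd.DataFrame:
    """The published per-sample uptake fits, long format (sample x cell line)."""
    return pd.read_csv(io.StringIO(_UPTAKE_FIT_CSV))


def reference_uptake_fits() -> list[UptakeFit]:
    """The published uptake fits as :class:`UptakeFit` objects.

    A missing printed U_P marks a series excluded by the R^2 < 0.8 rule; its
    R^2 is not printed, so excluded series carry r_squared = 0.0 and
    non-excluded ones 1.0 (placeholders — only the exclusion flag and U_P are
    meaningful here).
    """
    fits = []
    for _, row in uptake_fit_reference().iterrows():
        excluded = pd.isna(row["u_p_ref"])
        u_p = None if excluded else float(row["u_p_ref"])
        fits.append(
            UptakeFit(
                sample_id=row["sample_id"],
                cell_line=row["cell_line"],
                u_s=float(row["u_s"]),
                u_l=float(row["u_l"]),
                r_squared=0.0 if excluded else 1.0,
                excluded=bool(excluded),
                u_p_ref=u_p,
                u_p_ref_raw=u_p if u_p is not None else float("nan"),
                expected_error=None if pd.isna(row["er"]) else float(row["er"]),
                n_points=3,
            )
        )
    return fits
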