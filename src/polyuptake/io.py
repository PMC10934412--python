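"""Data model and tidy-table I/O for a styrene/MMA copolymer particle library.

Library members follow the ``Sty[X]MMA[Y][Z]`` naming scheme used for soap-free
emulsion copolymerizations of styrene (Sty) and methyl methacrylate (MMA):
``[X]`` is the molar percentage of Sty in the monomer feed, ``[Y]`` the
dimensionless monomer-concentration factor, and ``[Z]`` marks fluorescence
labelling (``F``) or its absence (``N``).  Physicochemical characterization
(copolymer composition from NIR, molecular weight from GPC, DLS/SEM diameters,
zeta potential) and per-load cellular-uptake measurements are carried in tidy
CSV/TSV tables with a snake_case canonical header; common short symbols
(``x``, ``Mn``, ``d``, ``PdI``, ``z``) are accepted as aliases on read.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DesignPoint",
    "ParticleRecord",
    "UptakeMeasurement",
    "SampleIDError",
    "CONC_AT_UNIT_FACTOR",
    "parse_sample_id",
    "format_sample_id",
    "read_library_table",
    "write_library_table",
    "records_to_frame",
    "read_uptake_table",
    "write_uptake_table",
    "measurements_to_frame",
    "group_uptake",
    "LIBRARY_COLUMNS",
    "UPTAKE_COLUMNS",
    "HEADER_ALIASES",
]

#: Monomer concentration (mol/L) at concentration factor 1.0.  Chosen so that
#: factor 0.8 maps to 2.10 mmol/mL; overridable wherever it is used.
CONC_AT_UNIT_FACTOR = 2.625

CELL_LINES = ("RAW", "HEK")


class SampleIDError(ValueError):
    """Raised when a sample identifier does not follow Sty<int>MMA<decimal><N|F>."""


@dataclass(frozen=True)
class DesignPoint:
    """One point of the synthesis design grid.

    Parameters
    ----------
    sty_feed
        Molar percentage of styrene in the monomer feed, 0-100.
    conc_factor
        Dimensionless concentration factor, 0 < f <= 1 in the library design.
    labeled
        Whether fluorescein-O-acrylate labelling was included.
    monomer_conc
        Total monomer concentration c in mol/L.  Defaults to
        ``conc_factor * CONC_AT_UNIT_FACTOR``.
    """

    sty_feed: float
    conc_factor: float
    labeled: bool
    monomer_conc: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not 0 <= self.sty_feed <= 100:
            raise ValueError(f"sty_feed must be in [0, 100], got {self.sty_feed}")
        if self.conc_factor <= 0:
            raise ValueError(f"conc_factor must be > 0, got {self.conc_factor}")
        if self.monomer_conc is None:
            object.__setattr__(
                self, "monomer_conc", self.conc_factor * CONC_AT_UNIT_FACTOR
            )
        if self.monomer_conc <= 0:
            raise ValueError(f"monomer_conc must be > 0, got {self.monomer_conc}")

    @property
    def sample_id(self) -> str:
        return format_sample_id(self)


@dataclass
class ParticleRecord:
    """Design variables plus physicochemical measurements for one library member.

    Units: ``x_sty`` mol % Sty in the copolymer (NIR calibration), ``mn`` in
    kg/mol (GPC), diameters in nm, ``zeta`` in mV (negative for these
    sulfate-initiated anionic latexes), solid contents in ug/mL.  ``d_sem`` and
    ``solid_measured`` may be missing (None).
    """

    sample_id: str
    design: DesignPoint
    x_sty: float
    mn: float
    d_dls: float
    pdi: float
    zeta: float
    d_sem: float | None = None
    solid_theoretical: float | None = None
    solid_measured: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.x_sty <= 100:
            raise ValueError(f"{self.sample_id}: x_sty must be in [0, 100]")
        if self.mn <= 0:
            raise ValueError(f"{self.sample_id}: mn must be > 0")
        if self.d_dls <= 0:
            raise ValueError(f"{self.sample_id}: d_dls must be > 0")
        if self.pdi < 0:
            raise ValueError(f"{self.sample_id}: pdi must be >= 0")
        if self.d_sem is not None and self.d_sem <= 0:
            raise ValueError(f"{self.sample_id}: d_sem must be > 0 when present")

    @property
    def minus_z(self) -> float:
        """Sign-flipped zeta potential, the form used in all multivariate runs."""
        return -self.zeta


@dataclass(frozen=True)
class UptakeMeasurement:
    """One (sample, cell line, particle load) flow-cytometry observation.

    ``load_p`` is the nominal particle load p in ug/mL; ``load_corrected`` the
    dimensionless solid-content-corrected load p-tilde (optional, recomputable);
    ``positive_pct`` the percentage of particle-positive cells U_P.
    """

    sample_id: str
    cell_line: str
    load_p: float
    positive_pct: float
    load_corrected: float | None = None

    def __post_init__(self) -> None:
        if self.cell_line not in CELL_LINES:
            raise ValueError(
                f"unknown cell_line {self.cell_line!r}; expected one of {CELL_LINES}"
            )
        if self.load_p <= 0:
            raise ValueError(f"{self.sample_id}: load_p must be > 0")
        if not 0 <= self.positive_pct <= 100:
            raise ValueError(
                f"{self.sample_id}: positive_pct must be in [0, 100], "
                f"got {self.positive_pct}"
            )


# --------------------------------------------------------------------------
# sample-ID nomenclature


_FEED_RE = re.compile(r"Sty(\d+)")
_FACTOR_RE = re.compile(r"(\d+(?:\.\d+)?)")


def parse_sample_id(
    sample_id: str, conc_at_unit_factor: float = CONC_AT_UNIT_FACTOR
) -> DesignPoint:
    """Parse a ``Sty<int>MMA<decimal><N|F>`` identifier into a :class:`DesignPoint`.

    >>> parse_sample_id("Sty25MMA0.8F")
    DesignPoint(sty_feed=25.0, conc_factor=0.8, labeled=True, monomer_conc=2.1)
    """
    s = sample_id.strip()
    m = _FEED_RE.match(s)
    if m is None:
        raise SampleIDError(
            f"malformed sample id {sample_id!r}: expected leading token "
            f"'Sty<int>', found {s[:6]!r}"
        )
    feed = int(m.group(1))
    pos = m.end()
    if s[pos : pos + 3] != "MMA":
        raise SampleIDError(
            f"malformed sample id {sample_id!r}: expected token 'MMA' after "
            f"'Sty{feed}', found {s[pos:pos + 3]!r}"
        )
    pos += 3
    m = _FACTOR_RE.match(s, pos)
    if m is None:
        raise SampleIDError(
            f"malformed sample id {sample_id!r}: expected a decimal "
            f"concentration factor after 'MMA', found {s[pos:pos + 4]!r}"
        )
    factor = float(m.group(1))
    pos = m.end()
    label_token = s[pos:]
    if label_token not in ("N", "F"):
        raise SampleIDError(
            f"malformed sample id {sample_id!r}: expected label token 'N' or "
            f"'F' at the end, found {label_token!r}"
        )
    if feed > 100:
        raise SampleIDError(
            f"malformed sample id {sample_id!r}: feed {feed} mol % exceeds 100"
        )
    return DesignPoint(
        sty_feed=float(feed),
        conc_factor=factor,
        labeled=(label_token == "F"),
        monomer_conc=factor * conc_at_unit_factor,
    )


def format_sample_id(design: DesignPoint) -> str:
    """Format a design point back into its ``Sty[X]MMA[Y][Z]`` identifier.

    Inverse of :func:`parse_sample_id` for all well-formed identifiers: the
    concentration factor keeps exactly the decimals needed, with at least one
    decimal place (``1.0``, not ``1``).
    """
    feed = int(round(design.sty_feed))
    factor = np.format_float_positional(design.conc_factor, trim="0")
    if factor.endswith("."):
        factor += "0"
    label = "F" if design.labeled else "N"
    return f"Sty{feed}MMA{factor}{label}"


# --------------------------------------------------------------------------
# tidy tables

LIBRARY_COLUMNS = [
    "sample_id",
    "sty_feed",
    "conc_factor",
    "monomer_conc",
    "labeled",
    "x_sty",
    "mn",
    "d_dls",
    "pdi",
    "d_sem",
    "zeta",
    "solid_theoretical",
    "solid_measured",
]

UPTAKE_COLUMNS = ["sample_id", "cell_line", "load_p", "positive_pct", "load_corrected"]

#: Short symbols accepted in table headers in place of the canonical names.
HEADER_ALIASES: Mapping[str, str] = {
    "id": "sample_id",
    "x": "x_sty",
    "Mn": "mn",
    "mn_kg_mol": "mn",
    "d": "d_dls",
    "d_DLS": "d_dls",
    "d_dls_nm": "d_dls",
    "PdI": "pdi",
    "d_SEM": "d_sem",
    "d_sem_nm": "d_sem",
    "z": "zeta",
    "zeta_mv": "zeta",
    "c": "monomer_conc",
    "p": "load_p",
    "U_P": "positive_pct",
    "p_tilde": "load_corrected",
}

_NA_VALUES = ["", "-", "NA", "nan"]


def _delimiter_for(source, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    if isinstance(source, (str, Path)) and str(source).lower().endswith(".tsv"):
        return "\t"
    return ","


def _read_table(source, delimiter, known_columns, numeric_columns) -> pd.DataFrame:
    sep = _delimiter_for(source, delimiter)
    try:
        df = pd.read_csv(source, sep=sep, na_values=_NA_VALUES, dtype=str)
    except pd.errors.EmptyDataError:
        logger.warning("empty table %r: returning no records", source)
        return pd.DataFrame(columns=known_columns)
    df = df.rename(columns={c: HEADER_ALIASES.get(c, c) for c in df.columns})
    unknown = [c for c in df.columns if c not in known_columns]
    if unknown:
        raise ValueError(f"unknown column(s) {unknown}; expected {known_columns}")
    for col in df.columns:
        if col in numeric_columns:
            try:
                # astype(float) parses via float(), which round-trips repr()
                # exactly (pd.to_numeric's fast parser loses ulps)
                df[col] = df[col].astype(float)
            except (ValueError, TypeError):
                bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()
                               & df[col].notna()].tolist()
                raise ValueError(
                    f"non-numeric value in numeric column {col!r} at row(s) {bad}"
                ) from None
    return df


def read_library_table(
    source,
    delimiter: str | None = None,
    conc_at_unit_factor: float = CONC_AT_UNIT_FACTOR,
    require_anionic: bool = True,
) -> list[ParticleRecord]:
    """Read a particle-library table (CSV/TSV) into :class:`ParticleRecord` objects.

    Missing values may be written as empty cells or ``-`` (the convention of the
    printed characterization tables).  ``require_anionic`` asserts zeta <= 0,
    which holds for persulfate-initiated latexes; disable for other chemistries.
    """
    numeric = set(LIBRARY_COLUMNS) - {"sample_id", "labeled"}
    df = _read_table(source, delimiter, LIBRARY_COLUMNS, numeric)
    records: list[ParticleRecord] = []
    for i, row in df.iterrows():
        design = parse_sample_id(row["sample_id"], conc_at_unit_factor)
        if "monomer_conc" in df.columns and not pd.isna(row.get("monomer_conc")):
            design = replace(design, monomer_conc=float(row["monomer_conc"]))
        zeta = float(row["zeta"])
        if require_anionic and zeta > 0:
            raise ValueError(
                f"row {i} ({row['sample_id']}): zeta {zeta} mV > 0; these latexes "
                "are anionic (pass require_anionic=False to allow)"
            )

        def _opt(col):
            v = row.get(col)
            return None if v is None or pd.isna(v) else float(v)

        records.append(
            ParticleRecord(
                sample_id=row["sample_id"],
                design=design,
                x_sty=float(row["x_sty"]),
                mn=float(row["mn"]),
                d_dls=float(row["d_dls"]),
                pdi=float(row["pdi"]),
                zeta=zeta,
                d_sem=_opt("d_sem"),
                solid_theoretical=_opt("solid_theoretical"),
                solid_measured=_opt("solid_measured"),
            )
        )
    return records


def records_to_frame(records: Iterable[ParticleRecord]) -> pd.DataFrame:
    """Tidy DataFrame (canonical columns) for a collection of particle records."""
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "sty_feed": r.design.sty_feed,
                "conc_factor": r.design.conc_factor,
                "monomer_conc": r.design.monomer_conc,
                "labeled": r.design.labeled,
                "x_sty": r.x_sty,
                "mn": r.mn,
                "d_dls": r.d_dls,
                "pdi": r.pdi,
                "d_sem": r.d_sem,
                "zeta": r.zeta,
                "solid_theoretical": r.solid_theoretical,
                "solid_measured": r.solid_measured,
            }
        )
    return pd.DataFrame(rows, columns=LIBRARY_COLUMNS)


def write_library_table(records: Iterable[ParticleRecord], target, delimiter=None):
    """Write records losslessly (full float repr; missing values as empty cells)."""
    df = records_to_frame(records)
    df.to_csv(target, sep=_delimiter_for(target, delimiter), index=False)


def read_uptake_table(source, delimiter: str | None = None) -> list[UptakeMeasurement]:
    """Read per-load cellular-uptake measurements.

    Duplicate (sample, cell line, load) rows are kept as replicates and logged.
    """
    numeric = {"load_p", "positive_pct", "load_corrected"}
    df = _read_table(source, delimiter, UPTAKE_COLUMNS, numeric)
    if len(df):
        dup = df.duplicated(subset=["sample_id", "cell_line", "load_p"], keep=False)
        if dup.any():
            keys = df.loc[dup, ["sample_id", "cell_line", "load_p"]]
            logger.info(
                "uptake table contains %d replicate rows for %d (sample, cell, "
                "load) keys; kept as replicates",
                int(dup.sum()),
                len(keys.drop_duplicates()),
            )
    out = []
    for _, row in df.iterrows():
        lc = row.get("load_corrected")
        out.append(
            UptakeMeasurement(
                sample_id=row["sample_id"],
                cell_line=row["cell_line"],
                load_p=float(row["load_p"]),
                positive_pct=float(row["positive_pct"]),
                load_corrected=None if lc is None or pd.isna(lc) else float(lc),
            )
        )
    return out


def measurements_to_frame(measurements: Iterable[UptakeMeasurement]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": m.sample_id,
            "cell_line": m.cell_line,
            "load_p": m.load_p,
            "positive_pct": m.positive_pct,
            "load_corrected": m.load_corrected,
        }
        for m in measurements
    ]
    return pd.DataFrame(rows, columns=UPTAKE_COLUMNS)


def write_uptake_table(measurements: Iterable[UptakeMeasurement], target, delimiter=None):
    measurements_to_frame(measurements).to_csv(
        target, sep=_delimiter_for(target, delimiter), index=False
    )


def group_uptake(
    measurements: Iterable[UptakeMeasurement],
) -> dict[tuple[str, str], list[UptakeMeasurement]]:
    """Group measurements by (sample_id, cell_line), preserving input order."""
    groups: dict[tuple[str, str], list[UptakeMeasurement]] = {}
    for m in measurements:
        groups.setdefault((m.sample_id, m.cell_line), []).append(m)
    return groups
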