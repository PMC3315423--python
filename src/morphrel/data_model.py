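"""Tabular data model for multi-site, test-retest morphometry studies.

The canonical interchange form is a long (tidy) table with one row per
subject x centre x visit x hemisphere x measure observation; sulcus-wise
measures additionally carry a sulcus label and the recognition algorithm
that produced them.  All downstream statistics (scanner-effect ANCOVA,
variance components, reliabilities) consume views of this table.

Derived morphometric quantities live here too: the cerebral hemisphere
volume (sum of the GM, WM and CSF volumes of that hemisphere) and the
fraction of cortex buried in sulci implied by the global sulcal index,
GSI / (1 + GSI).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyDesignError,
    IncompleteTripletError,
    ParseError,
    SchemaError,
    ValidationError,
)

#: Canonical column order of the interchange CSV.
COLUMNS = (
    "subject",
    "centre",
    "visit",
    "hemisphere",
    "measure",
    "sulcus",
    "algorithm",
    "value",
)

#: Columns that jointly key a single observation.
KEY_COLUMNS = COLUMNS[:-1]

#: Measures defined on a whole hemisphere.
GLOBAL_MEASURES = (
    "gm_volume",
    "wm_volume",
    "csf_volume",
    "hemisphere_volume",
    "gsi",
)

#: Measures defined per labelled sulcus.
SULCAL_MEASURES = ("sulcal_surface", "sulcal_depth")

MEASURES = GLOBAL_MEASURES + SULCAL_MEASURES

#: Units of each measure (volumes in cm^3, surface in mm^2, depth in mm).
UNITS = {
    "gm_volume": "cm3",
    "wm_volume": "cm3",
    "csf_volume": "cm3",
    "hemisphere_volume": "cm3",
    "gsi": "1",
    "sulcal_surface": "mm2",
    "sulcal_depth": "mm",
}

HEMISPHERES = ("left", "right")

#: Sulcus recognition algorithms whose labellings may be analysed separately.
ALGORITHMS = ("talairach", "global", "local", "markovian")


@dataclass(frozen=True)
class DesignSummary:
    """Size and completeness of the crossed design for one measure.

    ``complete`` is true once incomplete subjects (those lacking any
    centre x visit x hemisphere cell) have been moved to
    ``excluded_subjects``, mirroring the listwise-by-subject exclusion
    policy used for repeated-scan studies.
    """

    n_subjects: int
    n_centres: int
    n_visits: int
    n_hemispheres: int
    complete: bool
    excluded_subjects: tuple[str, ...] = ()

    @property
    def n_cells(self) -> int:
        return self.n_subjects * self.n_centres * self.n_visits * self.n_hemispheres


@dataclass
class MorphometryTable:
    """Validated long-format collection of morphometry observations.

    ``records`` is a :class:`pandas.DataFrame` with the canonical columns;
    ``sulcus`` and ``algorithm`` hold empty strings where inapplicable.
    """

    records: pd.DataFrame = field(repr=False)

    def __len__(self) -> int:
        return len(self.records)

    def measures(self) -> list[str]:
        return sorted(self.records["measure"].unique())

    def view(
        self,
        measure: str,
        *,
        algorithm: str | None = None,
        sulcus: str | None = None,
    ) -> pd.DataFrame:
        """Rows for one measure (and optionally one algorithm / sulcus)."""
        df = self.records
        m = df["measure"] == measure
        if algorithm is not None:
            m &= df["algorithm"] == algorithm
        if sulcus is not None:
            m &= df["sulcus"] == sulcus
        return df.loc[m].copy()

    def analysis_frame(
        self,
        measure: str,
        covariates: Sequence[str] = (),
        *,
        algorithm: str | None = None,
        sulcus: str | None = None,
    ) -> pd.DataFrame:
        """Measure view with covariate measures merged in as columns.

        Covariates (e.g. ``hemisphere_volume``, ``gsi``) are matched on
        subject x centre x visit x hemisphere; rows lacking a covariate
        value are dropped.
        """
        df = self.view(measure, algorithm=algorithm, sulcus=sulcus)
        keys = ["subject", "centre", "visit", "hemisphere"]
        for cov in covariates:
            cdf = self.view(cov)[keys + ["value"]].rename(columns={"value": cov})
            df = df.merge(cdf, on=keys, how="inner")
        return df.reset_index(drop=True)


def _schema_map(schema: Mapping[str, str] | None) -> dict[str, str]:
    mapping = {c: c for c in COLUMNS}
    if schema:
        unknown = set(schema) - set(COLUMNS)
        if unknown:
            raise SchemaError(f"unknown canonical columns in schema: {sorted(unknown)}")
        mapping.update(schema)
    return mapping


def _validate_records(df: pd.DataFrame, max_visits: int) -> pd.DataFrame:
    """Enforce the record invariants; raise with row-indexed diagnostics."""
    bad = ~np.isfinite(df["value"].to_numpy(dtype=float))
    if bad.any():
        rows = df.index[bad].tolist()[:10]
        raise ParseError(f"non-finite value(s) at row(s) {rows}")
    nonpos = df["value"].to_numpy(dtype=float) <= 0
    if nonpos.any():
        rows = df.index[nonpos].tolist()[:10]
        raise ValidationError(
            f"volumes, surfaces, depths and GSI must be > 0; offending row(s) {rows}"
        )

    bad_measure = ~df["measure"].isin(MEASURES)
    if bad_measure.any():
        names = sorted(df.loc[bad_measure, "measure"].unique())
        raise ValidationError(f"unknown measure(s): {names}")

    bad_hemi = ~df["hemisphere"].isin(HEMISPHERES)
    if bad_hemi.any():
        raise ValidationError(
            f"hemisphere must be one of {HEMISPHERES}; "
            f"offending row(s) {df.index[bad_hemi].tolist()[:10]}"
        )

    visits = df["visit"].to_numpy()
    bad_visit = (visits < 1) | (visits > max_visits)
    if bad_visit.any():
        raise ValidationError(
            f"visit must be in 1..{max_visits}; "
            f"offending row(s) {df.index[bad_visit].tolist()[:10]}"
        )

    is_sulcal = df["measure"].isin(SULCAL_MEASURES)
    missing_label = is_sulcal & ((df["sulcus"] == "") | (df["algorithm"] == ""))
    if missing_label.any():
        raise ValidationError(
            "sulcal measures require sulcus and algorithm labels; "
            f"offending row(s) {df.index[missing_label].tolist()[:10]}"
        )
    spurious = ~is_sulcal & ((df["sulcus"] != "") | (df["algorithm"] != ""))
    if spurious.any():
        raise ValidationError(
            "sulcus/algorithm labels are only valid for sulcal measures; "
            f"offending row(s) {df.index[spurious].tolist()[:10]}"
        )

    bad_alg = is_sulcal & ~df["algorithm"].isin(ALGORITHMS)
    if bad_alg.any():
        names = sorted(df.loc[bad_alg, "algorithm"].unique())
        raise ValidationError(f"unknown recognition algorithm(s): {names}")

    dup = df.duplicated(subset=list(KEY_COLUMNS), keep=False)
    if dup.any():
        key = df.loc[dup, list(KEY_COLUMNS)].iloc[0].to_dict()
        raise ValidationError(f"duplicate observation key: {key}")
    return df


def make_table(df: pd.DataFrame, *, max_visits: int = 2) -> MorphometryTable:
    """Build a validated :class:`MorphometryTable` from a tidy DataFrame."""
    df = df.copy()
    missing = set(COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"missing column(s): {sorted(missing)}")
    df = df[list(COLUMNS)]
    for col in ("subject", "centre", "hemisphere", "measure", "sulcus", "algorithm"):
        df[col] = df[col].fillna("").astype(str)
    try:
        df["visit"] = df["visit"].astype(int)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"visit column is not integer: {exc}") from exc
    values = pd.to_numeric(df["value"], errors="coerce")
    df["value"] = values.astype(float)
    _validate_records(df, max_visits)
    return MorphometryTable(records=df.reset_index(drop=True))


def load_morphometry_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    *,
    max_visits: int = 2,
) -> MorphometryTable:
    """Read and validate a long-format morphometry CSV/TSV.

    Parameters
    ----------
    path
        Delimited text file; ``.tsv`` is read tab-separated, anything else
        comma-separated.  A header row is required.
    schema
        Optional mapping from canonical column names to the file's column
        names, e.g. ``{"subject": "subj_id"}``.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    mapping = _schema_map(schema)
    missing = [src for src in mapping.values() if src not in raw.columns]
    if missing:
        raise SchemaError(f"mapped column(s) absent from {path.name}: {missing}")
    df = pd.DataFrame({canon: raw[src] for canon, src in mapping.items()})
    num = pd.to_numeric(df["value"].replace("", np.nan), errors="coerce")
    bad = ~np.isfinite(num.to_numpy(dtype=float))
    if bad.any():
        rows = df.index[bad].tolist()[:10]
        raise ParseError(f"non-numeric value(s) at row(s) {rows} of {path.name}")
    df["value"] = num
    try:
        df["visit"] = pd.to_numeric(df["visit"]).astype(int)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"non-integer visit in {path.name}: {exc}") from exc
    return make_table(df, max_visits=max_visits)


def write_table(table: MorphometryTable, path: str | Path) -> None:
    """Write the canonical CSV/TSV form (round-trips with the loader)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    table.records.to_csv(path, sep=sep, index=False)


def validate_design(
    table: MorphometryTable,
    measure: str,
    *,
    algorithm: str | None = None,
    sulcus: str | None = None,
) -> DesignSummary:
    """Check crossing/balance of the design for one measure.

    Subjects missing any centre x visit x hemisphere cell are excluded
    (listwise by subject), and the summary reports the remaining fully
    crossed design.
    """
    df = table.view(measure, algorithm=algorithm, sulcus=sulcus)
    if df.empty:
        raise EmptyDesignError(f"no records for measure {measure!r}")
    centres = sorted(df["centre"].unique())
    visits = sorted(df["visit"].unique())
    hemis = sorted(df["hemisphere"].unique())
    expected = len(centres) * len(visits) * len(hemis)
    counts = df.groupby("subject").size()
    complete_subjects = sorted(counts.index[counts == expected])
    excluded = tuple(sorted(set(counts.index) - set(complete_subjects)))
    if not complete_subjects:
        raise EmptyDesignError(
            f"no subject has complete {len(centres)}x{len(visits)}x{len(hemis)} "
            f"data for measure {measure!r}"
        )
    return DesignSummary(
        n_subjects=len(complete_subjects),
        n_centres=len(centres),
        n_visits=len(visits),
        n_hemispheres=len(hemis),
        complete=True,
        excluded_subjects=excluded,
    )


def complete_view(
    table: MorphometryTable,
    measure: str,
    *,
    algorithm: str | None = None,
    sulcus: str | None = None,
) -> tuple[pd.DataFrame, DesignSummary]:
    """Measure view restricted to subjects with complete designs."""
    summary = validate_design(table, measure, algorithm=algorithm, sulcus=sulcus)
    df = table.view(measure, algorithm=algorithm, sulcus=sulcus)
    df = df[~df["subject"].isin(summary.excluded_subjects)].reset_index(drop=True)
    return df, summary


def derive_hemisphere_volume(table: MorphometryTable) -> MorphometryTable:
    """Add hemisphere_volume = GM + WM + CSF per design cell.

    The cerebral hemisphere volume is the sum of the grey-matter,
    white-matter and CSF volumes of that hemisphere.  Idempotent: cells
    that already carry a hemisphere_volume record are left untouched.
    """
    df = table.records
    keys = ["subject", "centre", "visit", "hemisphere"]
    triplet = df[df["measure"].isin(("gm_volume", "wm_volume", "csf_volume"))]
    if triplet.empty:
        raise IncompleteTripletError("no GM/WM/CSF volume records present")
    wide = triplet.pivot_table(
        index=keys, columns="measure", values="value", aggfunc="first"
    )
    for m in ("gm_volume", "wm_volume", "csf_volume"):
        if m not in wide.columns:
            wide[m] = np.nan
    incomplete = wide[wide.isna().any(axis=1)]
    if not incomplete.empty:
        key = dict(zip(keys, incomplete.index[0]))
        raise IncompleteTripletError(f"incomplete GM/WM/CSF triplet for cell {key}")
    existing = set(
        map(tuple, df.loc[df["measure"] == "hemisphere_volume", keys].to_numpy())
    )
    total = wide.sum(axis=1)
    new_rows = [
        dict(zip(keys, idx))
        | {"measure": "hemisphere_volume", "sulcus": "", "algorithm": "", "value": v}
        for idx, v in total.items()
        if tuple(idx) not in existing
    ]
    if not new_rows:
        return table
    out = pd.concat([df, pd.DataFrame(new_rows)], ignore_index=True)
    return make_table(out, max_visits=int(df["visit"].max()))


def buried_fraction(gsi):
    """Fraction of the cortex buried in sulci implied by a global sulcal
    index: GSI / (1 + GSI).

    The GSI is the ratio of the folded (sulcal) cortical surface to the
    outer hull surface, so buried/total = GSI/(1+GSI).  Accepts scalars or
    arrays; strictly increasing, with range (0, 1) for GSI in (0, inf).
    """
    g = np.asarray(gsi, dtype=float)
    if np.any(~np.isfinite(g)) or np.any(g <= 0):
        raise ValueError("GSI must be finite and > 0")
    out = g / (1.0 + g)
    return float(out) if np.isscalar(gsi) or out.ndim == 0 else out
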