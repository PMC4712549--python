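"""Readers, writers and the canonical data model for TaqMan LDA CT exports.

The on-disk canonical form is long (tidy) tab-delimited text:

    assay_id  mirna_name  plate  sample_id  ct  duplicate_group

``ct`` is a threshold cycle in ``[0, max_cycle]`` or the instrument's
"Undetermined" call, kept internally as a NaN sentinel so that
"not detected" stays distinct from any numeric cycle (the on/off rule
downstream depends on that distinction).  A wide dialect (one row per
assay, one column per sample) is accepted on read and converted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "UNDETERMINED",
    "FormatError",
    "ValidationError",
    "CtMatrix",
    "SampleSheet",
    "is_undetermined",
    "read_ct_table",
    "write_ct_table",
    "read_sample_sheet",
    "write_sample_sheet",
]

#: Sentinel for wells where no amplification crossed threshold.  NaN, not a
#: large cycle number: arithmetic must never silently treat non-detection as
#: "detected late".
UNDETERMINED: float = float("nan")

#: Strings (case-insensitive, stripped) that map to the sentinel on read.
_UNDETERMINED_STRINGS = {"undetermined", "na", ""}

CT_COLUMNS = ["assay_id", "mirna_name", "plate", "sample_id", "ct", "duplicate_group"]
GROUPS = ("knockdown", "control")
PLATES = ("A", "B")


class FormatError(ValueError):
    """A file does not match the documented dialect (e.g. missing column)."""


class ValidationError(ValueError):
    """Structurally parseable input violates a data-model invariant."""


def is_undetermined(ct) -> bool | np.ndarray | pd.Series:
    """True where a CT value is the non-detection sentinel."""
    if np.isscalar(ct):
        return isinstance(ct, float) and math.isnan(ct)
    return pd.isna(ct)


@dataclass
class CtMatrix:
    """Raw threshold-cycle values per (assay, sample) with plate metadata.

    Parameters
    ----------
    data : pandas.DataFrame
        Long-form table with columns ``assay_id, mirna_name, plate,
        sample_id, ct, duplicate_group``.  ``ct`` holds NaN for
        "Undetermined" wells; ``duplicate_group`` is empty for singleton
        assays and a shared key for the duplicated ones.
    max_cycle : float
        Instrument run length; numeric CTs must lie in ``[0, max_cycle]``.
    """

    data: pd.DataFrame
    max_cycle: float = 40.0

    def __post_init__(self) -> None:
        missing = [c for c in CT_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"CT table is missing required column(s): {missing}")
        df = self.data.loc[:, CT_COLUMNS].copy()
        df["ct"] = pd.to_numeric(df["ct"], errors="raise").astype(float)
        df["duplicate_group"] = df["duplicate_group"].fillna("").astype(str)
        bad_plate = ~df["plate"].isin(PLATES)
        if bad_plate.any():
            raise ValidationError(
                f"unknown plate label(s) {sorted(df.loc[bad_plate, 'plate'].unique())}; "
                f"allowed: {list(PLATES)}"
            )
        numeric = df["ct"].notna()
        out_of_range = numeric & ((df["ct"] < 0) | (df["ct"] > self.max_cycle))
        if out_of_range.any():
            idx = df.index[out_of_range][0]
            raise ValidationError(
                f"ct value {df.loc[idx, 'ct']} outside [0, {self.max_cycle}] at row {idx}"
            )
        dup = df.duplicated(subset=["assay_id", "sample_id"])
        if dup.any():
            pair = df.loc[dup.idxmax(), ["assay_id", "sample_id"]].tolist()
            raise ValidationError(f"duplicate (assay_id, sample_id) record: {tuple(pair)}")
        grouped = df.loc[df["duplicate_group"] != ""]
        if not grouped.empty:
            n_names = grouped.groupby("duplicate_group")["mirna_name"].nunique()
            bad = n_names[n_names > 1]
            if not bad.empty:
                raise ValidationError(
                    f"duplicate_group(s) {list(bad.index)} mix different mirna_name values"
                )
        self.data = df.reset_index(drop=True)

    # -- convenience views -------------------------------------------------
    @property
    def assay_ids(self) -> pd.Index:
        return pd.Index(self.data["assay_id"].unique())

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.data["sample_id"].unique())

    def pivot(self) -> pd.DataFrame:
        """Assay x sample CT grid (NaN where undetermined)."""
        wide = self.data.pivot(index="assay_id", columns="sample_id", values="ct")
        return wide.loc[self.assay_ids, self.sample_ids]

    def assay_annotation(self) -> pd.DataFrame:
        """Per-assay metadata (mirna_name, plate, duplicate_group)."""
        ann = self.data.drop_duplicates("assay_id").set_index("assay_id")
        return ann[["mirna_name", "plate", "duplicate_group"]]

    def plate_of(self) -> pd.Series:
        return self.assay_annotation()["plate"]


@dataclass
class SampleSheet:
    """Sample-to-group assignment for the two-arm knockdown design."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("sample_id", "group") if c not in self.data.columns]
        if missing:
            raise FormatError(f"sample sheet is missing required column(s): {missing}")
        df = self.data.copy()
        if "label" not in df.columns:
            df["label"] = ""
        df = df.loc[:, ["sample_id", "group", "label"]]
        df["label"] = df["label"].fillna("").astype(str)
        bad = ~df["group"].isin(GROUPS)
        if bad.any():
            raise ValidationError(
                f"unknown group label(s) {sorted(df.loc[bad, 'group'].unique())}; "
                f"allowed: {list(GROUPS)}"
            )
        if df["sample_id"].duplicated().any():
            raise ValidationError("sample_id values must be unique")
        for g in GROUPS:
            if not (df["group"] == g).any():
                raise ValidationError(f"empty group: {g}")
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.data["sample_id"])

    def group_samples(self, group: str) -> list[str]:
        return self.data.loc[self.data["group"] == group, "sample_id"].tolist()

    @property
    def knockdown(self) -> list[str]:
        return self.group_samples("knockdown")

    @property
    def control(self) -> list[str]:
        return self.group_samples("control")


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _parse_ct_cell(value) -> float:
    if pd.isna(value):
        return UNDETERMINED
    if isinstance(value, str):
        if value.strip().lower() in _UNDETERMINED_STRINGS:
            return UNDETERMINED
        try:
            return float(value)
        except ValueError as exc:
            raise FormatError(f"unparseable ct value {value!r}") from exc
    return float(value)


def read_ct_table(path, dialect: str = "long", *, sep=None, max_cycle: float = 40.0) -> CtMatrix:
    """Read a CT export in the long (tidy) or wide (assay x sample) dialect.

    ``sep=None`` sniffs the delimiter (tab or comma).  The literal strings
    "Undetermined", "undetermined", "NA" and empty cells become the
    non-detection sentinel; everything else must parse as a cycle number.
    """
    if dialect not in ("long", "wide"):
        raise ValueError(f"unknown dialect {dialect!r}; use 'long' or 'wide'")
    raw = pd.read_csv(path, sep=sep, engine="python", dtype=str,
                      keep_default_na=False, skipinitialspace=True)
    if dialect == "long":
        missing = [c for c in CT_COLUMNS[:5] if c not in raw.columns]
        if missing:
            raise FormatError(f"CT table {path} is missing column(s): {missing}")
        if "duplicate_group" not in raw.columns:
            raw["duplicate_group"] = ""
        long = raw
    else:
        meta_cols = ["assay_id", "mirna_name", "plate"]
        missing = [c for c in meta_cols if c not in raw.columns]
        if missing:
            raise FormatError(f"wide CT table {path} is missing column(s): {missing}")
        if "duplicate_group" not in raw.columns:
            raw["duplicate_group"] = ""
        sample_cols = [c for c in raw.columns if c not in meta_cols + ["duplicate_group"]]
        if not sample_cols:
            raise FormatError(f"wide CT table {path} has no sample columns")
        long = raw.melt(id_vars=meta_cols + ["duplicate_group"],
                        value_vars=sample_cols,
                        var_name="sample_id", value_name="ct")
    long = long.copy()
    long["ct"] = [_parse_ct_cell(v) for v in long["ct"]]
    return CtMatrix(long[CT_COLUMNS], max_cycle=max_cycle)


def write_ct_table(ct: CtMatrix, path, *, precision: int = 4) -> None:
    """Write the long canonical form; sentinel cells serialize as "Undetermined"."""
    df = ct.data.copy()
    df["ct"] = [
        "Undetermined" if math.isnan(v) else f"{v:.{precision}f}" for v in df["ct"]
    ]
    df.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path, *, sep=None) -> SampleSheet:
    raw = pd.read_csv(path, sep=sep, engine="python", dtype=str, keep_default_na=False)
    return SampleSheet(raw)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.data.to_csv(path, sep="\t", index=False)
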