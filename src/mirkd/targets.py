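"""miRNA-target interaction (MTI) filtering and signed context+ scoring.

Curated interactions carry an experimental-evidence class; predicted ones
carry a TargetScan-style context+ score (more negative = stronger predicted
repression).  The direction-aware aggregate keeps a score negative when the
targeting miRNA is down-regulated upon knockdown and flips it positive when
the miRNA is up-regulated, so a gene's signed sum reflects the net
predicted shift of repression pressure; genes with |sum| below the cutoff
(those targeted about equally by up- and down-regulated miRNAs) drop out.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import FormatError, ValidationError

__all__ = [
    "MTI_COLUMNS",
    "read_mti_table",
    "validate_mti",
    "FilterReport",
    "filter_mti",
    "signed_scores",
    "signed_gene_score",
    "term_signed_score",
    "ontology_presence_table",
    "read_gene_term_map",
]

MTI_COLUMNS = ["mirna_id", "gene_id", "source", "evidence", "context_score"]
SOURCES = ("curated", "predicted")
EVIDENCE_RANK = {"none": 0, "weak": 1, "strong": 2}
DIRECTIONS = ("up_in_knockdown", "down_in_knockdown")


def validate_mti(table: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalize an MTI table.

    Duplicate predicted (mirna, gene) rows are assumed to be site-level
    exports and are summed into one per-gene aggregate with a warning.
    """
    missing = [c for c in MTI_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"MTI table is missing column(s): {missing}")
    df = table.loc[:, MTI_COLUMNS].copy()
    bad_src = ~df["source"].isin(SOURCES)
    if bad_src.any():
        raise ValidationError(
            f"unknown source value(s) {sorted(df.loc[bad_src, 'source'].unique())}"
        )
    df["context_score"] = pd.to_numeric(df["context_score"], errors="coerce")
    df["evidence"] = df["evidence"].fillna("none").replace("", "none")
    bad_ev = ~df["evidence"].isin(EVIDENCE_RANK)
    if bad_ev.any():
        raise ValidationError(
            f"unknown evidence class(es) {sorted(df.loc[bad_ev, 'evidence'].unique())}"
        )
    pred = df["source"] == "predicted"
    if df.loc[pred, "context_score"].isna().any():
        raise ValidationError("predicted MTI rows must carry a context_score")
    if (df.loc[pred, "context_score"] > 0).any():
        raise ValidationError("context scores must be <= 0")
    dup_pred = df.loc[pred].duplicated(subset=["mirna_id", "gene_id"], keep=False)
    if dup_pred.any():
        warnings.warn(
            "summing duplicate predicted (mirna, gene) rows (site-level export assumed)"
        )
        pred_rows = (
            df.loc[pred]
            .groupby(["mirna_id", "gene_id"], as_index=False)
            .agg(source=("source", "first"), evidence=("evidence", "first"),
                 context_score=("context_score", "sum"))
        )
        df = pd.concat([df.loc[~pred], pred_rows], ignore_index=True)
    if df.duplicated(subset=["mirna_id", "gene_id", "source"]).any():
        raise ValidationError("(mirna_id, gene_id, source) rows must be unique")
    return df.reset_index(drop=True)


def read_mti_table(path, *, sep="\t") -> pd.DataFrame:
    raw = pd.read_csv(path, sep=sep, dtype={"mirna_id": str, "gene_id": str},
                      keep_default_na=True)
    return validate_mti(raw)


def read_gene_term_map(path, *, sep="\t") -> pd.DataFrame:
    """Gene -> ontology term map: columns gene_id, term_id[, term_name]."""
    raw = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in ("gene_id", "term_id") if c not in raw.columns]
    if missing:
        raise FormatError(f"gene-term map is missing column(s): {missing}")
    if "term_name" not in raw.columns:
        raw["term_name"] = raw["term_id"]
    return raw[["gene_id", "term_id", "term_name"]].drop_duplicates().reset_index(drop=True)


@dataclass
class FilterReport:
    """Row-count bookkeeping of the evidence and expression filters."""

    n_input: int
    n_removed_evidence: int
    n_removed_unexpressed: int
    n_output: int

    def reconciles(self) -> bool:
        return self.n_input == (self.n_output + self.n_removed_evidence
                                + self.n_removed_unexpressed)


def filter_mti(table: pd.DataFrame, expressed_genes,
               evidence_min: str = "strong") -> tuple[pd.DataFrame, FilterReport]:
    """Evidence filter (curated rows only) then expression-background filter.

    Curated rows below ``evidence_min`` are removed; predicted rows pass the
    evidence filter untouched.  Then every row whose gene is not in the
    expressed background is removed.  Returns the filtered table and the
    removal counts.
    """
    expressed = set(expressed_genes)
    if not expressed:
        raise ValidationError("expressed_genes must be non-empty")
    if evidence_min not in EVIDENCE_RANK:
        raise ValueError(f"evidence_min must be one of {sorted(EVIDENCE_RANK)}")
    df = validate_mti(table)
    n_input = len(df)
    min_rank = EVIDENCE_RANK[evidence_min]
    keep_ev = (df["source"] == "predicted") | (
        df["evidence"].map(EVIDENCE_RANK) >= min_rank
    )
    after_ev = df[keep_ev]
    keep_expr = after_ev["gene_id"].isin(expressed)
    out = after_ev[keep_expr].reset_index(drop=True)
    report = FilterReport(
        n_input=n_input,
        n_removed_evidence=int((~keep_ev).sum()),
        n_removed_unexpressed=int((~keep_expr).sum()),
        n_output=len(out),
    )
    return out, report


def _directions_series(directions) -> pd.Series:
    d = pd.Series(directions)
    bad = ~d.isin(DIRECTIONS)
    if bad.any():
        raise ValidationError(
            f"unknown direction value(s) {sorted(d[bad].unique())}; "
            f"allowed: {list(DIRECTIONS)}"
        )
    return d


def signed_scores(table: pd.DataFrame, directions) -> pd.DataFrame:
    """Predicted MTI rows with a per-interaction signed context+ score.

    Down-regulated miRNAs keep the (negative) context+ score; up-regulated
    miRNAs contribute the sign-flipped (positive) value.
    """
    d = _directions_series(directions)
    pred = table[table["source"] == "predicted"].copy()
    missing = sorted(set(pred["mirna_id"]) - set(d.index))
    if missing:
        raise ValidationError(f"miRNA(s) without a direction: {missing}")
    dir_of = d.reindex(pred["mirna_id"]).to_numpy()
    score = pred["context_score"].to_numpy(dtype=float)
    pred["signed_score"] = np.where(dir_of == "down_in_knockdown", score, -score)
    return pred


def signed_gene_score(table: pd.DataFrame, directions,
                      cutoff: float = 0.4) -> pd.DataFrame:
    """Per-gene signed context+ sums and the |sum| >= cutoff flag."""
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    scored = signed_scores(table, directions)
    grp = scored.groupby("gene_id")
    out = pd.DataFrame(
        {
            "signed_sum": grp["signed_score"].sum(),
            "n_mti": grp.size(),
        }
    )
    out["passes_cutoff"] = out["signed_sum"].abs() >= cutoff
    return out.sort_index()


def term_signed_score(gene_scores: pd.DataFrame, table: pd.DataFrame,
                      directions, gene_terms: pd.DataFrame,
                      include_failing: bool = False) -> pd.DataFrame:
    """Per-ontology-term sums of signed MTI scores.

    Each term sums the signed scores of all MTIs of its member genes that
    passed the gene-level cutoff (``include_failing=True`` lifts that
    restriction).  A negative term sum marks predominant targeting by
    down-regulated miRNAs.  Terms with no scored member genes are omitted
    with a warning.
    """
    scored = signed_scores(table, directions)
    eligible = gene_scores if include_failing else gene_scores[gene_scores["passes_cutoff"]]
    scored = scored[scored["gene_id"].isin(eligible.index)]
    rows, skipped = [], []
    for (term_id, term_name), members in gene_terms.groupby(["term_id", "term_name"]):
        hits = scored[scored["gene_id"].isin(set(members["gene_id"]))]
        if hits.empty:
            skipped.append(term_id)
            continue
        rows.append({
            "term_id": term_id,
            "term_name": term_name,
            "signed_term_score": hits["signed_score"].sum(),
            "n_mti": len(hits),
            "n_genes": hits["gene_id"].nunique(),
        })
    if skipped:
        warnings.warn(f"omitted {len(skipped)} term(s) with no scored member genes")
    return pd.DataFrame(rows, columns=["term_id", "term_name", "signed_term_score",
                                       "n_mti", "n_genes"]).set_index("term_id")


def _canonical_label(label: str, synonym_map: dict[str, str] | None) -> str:
    norm = re.sub(r"\s+", " ", str(label)).strip().casefold()
    if synonym_map:
        norm_map = {re.sub(r"\s+", " ", k).strip().casefold(): v
                    for k, v in synonym_map.items()}
        return norm_map.get(norm, norm)
    return norm


def ontology_presence_table(collections: dict[str, list[str]],
                            synonym_map: dict[str, str] | None = None,
                            expression_key: str | None = None) -> pd.DataFrame:
    """Cross-dataset presence/absence matrix of enriched term labels.

    Rows are canonical labels present in at least two of the named
    collections.  Labels are compared case-insensitively with whitespace
    collapsed, then mapped through ``synonym_map``.  If ``expression_key``
    names the gene-expression collection, terms absent from it but present
    in >= 2 target-gene collections are flagged ``mirna_specific``.
    """
    if len(collections) < 2:
        raise ValidationError("need at least 2 named collections")
    canon = {
        name: {_canonical_label(t, synonym_map) for t in terms}
        for name, terms in collections.items()
    }
    all_terms = sorted(set().union(*canon.values()))
    rows = []
    for term in all_terms:
        present = {name: term in terms for name, terms in canon.items()}
        if sum(present.values()) < 2:
            continue
        row = {"term": term, **present}
        if expression_key is not None:
            others = [v for k, v in present.items() if k != expression_key]
            row["mirna_specific"] = (not present.get(expression_key, False)) and sum(others) >= 2
        rows.append(row)
    cols = ["term"] + list(collections)
    if expression_key is not None:
        cols.append("mirna_specific")
    return pd.DataFrame(rows, columns=cols).set_index("term")
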