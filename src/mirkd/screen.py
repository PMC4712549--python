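"""End-to-end workflows.

``MirnaScreen`` runs the qPCR-array differential-expression screen:
CT ingestion -> log2 conversion -> per-plate cyclic loess -> detection
partition -> moderated t with BH adjustment -> on/off lower limits ->
duplicate concordance -> candidate assembly.  ``TargetAnalysis`` runs the
downstream target workflow: evidence/expression MTI filtering -> signed
context+ gene and term sums -> ontology enrichment with the
fold-enrichment/p screening rule.  Both are thin, deterministic
compositions of the library functions and write reproducibility manifests
alongside their tables.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diffexpr import (DEResults, ModeratedTTest, OnOffRecord,
                       assemble_candidates, detection_partition,
                       onoff_lower_limit)
from .enrich import enrichment_test, filter_enriched
from .io import CtMatrix, SampleSheet, ValidationError
from .normalize import ct_to_log2, cyclic_loess
from .targets import filter_mti, signed_gene_score, term_signed_score

__all__ = ["ScreenConfig", "MirnaScreen", "ScreenResults",
           "TargetAnalysis", "TargetAnalysisResults"]


@dataclass
class ScreenConfig:
    """Tunable parameters of the miRNA screen."""

    ct_cutoff: float = 34.5
    max_cycle: float = 40.0
    alpha: float = 0.05
    use_adjusted: bool = False
    loess_span: float = 0.7
    loess_max_iter: int = 3
    loess_tol: float = 1e-3
    loess_min_common: int = 10
    normalize: bool = True


class ScreenResults:
    """Outputs of one screen run: candidates, per-feature statistics,
    detection partition, and the normalized expression matrix."""

    def __init__(self, candidates: pd.DataFrame, de: DEResults | None,
                 onoff: list[OnOffRecord], partition, normalized,
                 config: ScreenConfig, n_dropped_incomplete: int):
        self.candidates = candidates
        self.de = de
        self.onoff = onoff
        self.partition = partition
        self.normalized = normalized
        self.config = config
        self.n_dropped_incomplete = n_dropped_incomplete

    def summary(self) -> str:
        part = self.partition
        n_onoff = sum(self.candidates["status"] == "on_off")
        n_sig = sum(self.candidates["status"] == "significant")
        lines = [
            "miRNA knockdown screen",
            f"  assays: detected {len(part.detected)}, "
            f"low-expression excluded {len(part.excluded)}, on/off {len(part.onoff)}",
            f"  dropped (incompletely detected): {self.n_dropped_incomplete}",
        ]
        if self.de is not None:
            lines.append(
                f"  moderated t: prior df {self.de.prior_df:.4g}, "
                f"prior var {self.de.prior_var:.4g}"
            )
        rule = "BH-adjusted" if self.config.use_adjusted else "raw"
        lines += [
            f"  candidates at {rule} p < {self.config.alpha}: "
            f"{len(self.candidates)} ({n_sig} significant + {n_onoff} on/off)",
        ]
        return "\n".join(lines)

    def to_directory(self, path) -> None:
        """Write candidates.tsv, de.tsv and a reproducibility manifest."""
        out = Path(path)
        out.mkdir(parents=True, exist_ok=True)
        cand = self.candidates.copy()
        for col in ("p", "p_adj"):
            cand[col] = [("n.c." if np.isnan(v) else f"{v:.6g}") for v in cand[col]]
        cand.to_csv(out / "candidates.tsv", sep="\t", index=False)
        if self.de is not None:
            self.de.frame.to_csv(out / "de.tsv", sep="\t",
                                 index_label="feature_id", float_format="%.6g")
        manifest = {
            "tool": "mirkd",
            "version": __version__,
            "workflow": "mirna_screen",
            "config": asdict(self.config),
            "n_candidates": int(len(self.candidates)),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


class MirnaScreen:
    """The qPCR-array screen as a fit-able model over (CtMatrix, SampleSheet)."""

    def __init__(self, ct: CtMatrix, samples: SampleSheet,
                 config: ScreenConfig | None = None, **overrides):
        if ct.data.empty:
            raise ValidationError("empty CT table")
        unresolved = set(ct.sample_ids) - set(samples.sample_ids)
        if unresolved:
            raise ValidationError(f"CT samples missing from sample sheet: {sorted(unresolved)}")
        self.ct = ct
        self.samples = samples
        self.config = config or ScreenConfig(**overrides)
        if config is not None and overrides:
            raise ValueError("pass either a config object or keyword overrides, not both")

    def fit(self) -> ScreenResults:
        cfg = self.config
        part = detection_partition(self.ct, self.samples, cfg.ct_cutoff)
        x = ct_to_log2(self.ct, cfg.max_cycle)
        if cfg.normalize:
            x = cyclic_loess(
                x, self.ct.plate_of(), span=cfg.loess_span,
                max_iter=cfg.loess_max_iter, tol=cfg.loess_tol,
                min_common=cfg.loess_min_common,
            )
        detected = x.values.loc[part.detected, list(self.samples.sample_ids)]
        complete = detected.dropna()
        n_dropped = len(detected) - len(complete)
        de = None
        if len(complete):
            de = ModeratedTTest(complete, self.samples).fit()
        onoff = [
            onoff_lower_limit(self.ct, a, self.samples, cfg.ct_cutoff, partition=part)
            for a in sorted(part.onoff)
        ]
        dup_groups = self.ct.assay_annotation()["duplicate_group"]
        candidates = assemble_candidates(
            de, onoff, alpha=cfg.alpha,
            duplicate_groups=dup_groups, use_adjusted=cfg.use_adjusted,
        )
        return ScreenResults(candidates, de, onoff, part, x, cfg, n_dropped)


@dataclass
class TargetAnalysisConfig:
    cutoff: float = 0.4
    evidence_min: str = "strong"
    method: str = "ease"
    fe_min: float = 1.5
    p_max: float = 0.1
    include_failing: bool = False


class TargetAnalysisResults:
    def __init__(self, mti, filter_report, gene_scores, term_scores,
                 enrichment, enriched, config):
        self.mti = mti
        self.filter_report = filter_report
        self.gene_scores = gene_scores
        self.term_scores = term_scores
        self.enrichment = enrichment
        self.enriched = enriched
        self.config = config

    def summary(self) -> str:
        r = self.filter_report
        n_pass = int(self.gene_scores["passes_cutoff"].sum()) if len(self.gene_scores) else 0
        lines = [
            "miRNA target analysis",
            f"  MTI filter: {r.n_input} -> {r.n_output} "
            f"(evidence removed {r.n_removed_evidence}, "
            f"unexpressed removed {r.n_removed_unexpressed})",
            f"  genes passing |signed sum| >= {self.config.cutoff}: {n_pass}",
        ]
        if self.enrichment is None:
            lines.append("  enrichment skipped: no genes passed the cutoff")
        else:
            lines.append(
                f"  enriched terms (FE >= {self.config.fe_min}, "
                f"p < {self.config.p_max}, {self.config.method}): {len(self.enriched)}"
            )
        return "\n".join(lines)

    def to_directory(self, path) -> None:
        out = Path(path)
        out.mkdir(parents=True, exist_ok=True)
        self.gene_scores.to_csv(out / "gene_scores.tsv", sep="\t", float_format="%.6g")
        self.term_scores.to_csv(out / "term_scores.tsv", sep="\t", float_format="%.6g")
        if self.enrichment is not None:
            self.enrichment.to_csv(out / "enrichment.tsv", sep="\t", float_format="%.6g")
            self.enriched.to_csv(out / "enriched_terms.tsv", sep="\t", float_format="%.6g")
        manifest = {
            "tool": "mirkd",
            "version": __version__,
            "workflow": "target_analysis",
            "config": asdict(self.config),
            "filter_report": asdict(self.filter_report),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


class TargetAnalysis:
    """Signed target scoring plus enrichment for a screened miRNA set.

    Parameters
    ----------
    mti : DataFrame
        Combined curated + predicted interaction table.
    directions : mapping
        miRNA -> up_in_knockdown / down_in_knockdown (e.g. from the sign of
        the screen's candidate log2 fold changes).
    expressed_genes : iterable
        The cellular-context expression background; also the enrichment
        background.
    gene_terms : DataFrame
        gene_id / term_id / term_name annotation map.
    """

    def __init__(self, mti: pd.DataFrame, directions, expressed_genes,
                 gene_terms: pd.DataFrame,
                 config: TargetAnalysisConfig | None = None, **overrides):
        self.mti = mti
        self.directions = directions
        self.expressed_genes = list(expressed_genes)
        self.gene_terms = gene_terms
        self.config = config or TargetAnalysisConfig(**overrides)
        if config is not None and overrides:
            raise ValueError("pass either a config object or keyword overrides, not both")

    def fit(self) -> TargetAnalysisResults:
        cfg = self.config
        filtered, report = filter_mti(self.mti, self.expressed_genes,
                                      evidence_min=cfg.evidence_min)
        gene_scores = signed_gene_score(filtered, self.directions, cutoff=cfg.cutoff)
        passing = gene_scores[gene_scores["passes_cutoff"]]
        if passing.empty:
            empty_terms = pd.DataFrame(
                columns=["term_name", "signed_term_score", "n_mti", "n_genes"])
            return TargetAnalysisResults(filtered, report, gene_scores,
                                         empty_terms, None, None, cfg)
        term_scores = term_signed_score(gene_scores, filtered, self.directions,
                                        self.gene_terms,
                                        include_failing=cfg.include_failing)
        background = set(self.expressed_genes)
        gene_list = set(passing.index) & background
        enrichment = enrichment_test(gene_list, background, self.gene_terms,
                                     method=cfg.method)
        enriched = filter_enriched(enrichment, fe_min=cfg.fe_min, p_max=cfg.p_max)
        return TargetAnalysisResults(filtered, report, gene_scores, term_scores,
                                     enrichment, enriched, cfg)
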