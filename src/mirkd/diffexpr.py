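"""Differential-expression calling for the knockdown-vs-control contrast.

The moderated two-sample t-test shrinks per-feature variances toward an
empirical-Bayes prior (d0, s0^2) estimated across all features by moment
matching of the log residual variances against a scaled F distribution;
per-feature posterior variance is the df-weighted blend

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

and the moderated t uses d0 + d_g degrees of freedom.  Around it sit the
qPCR-specific rules: the high-CT detection filter, the on/off lower-limit
fold-change bound for features detected in only one treatment arm, the
duplicate-assay concordance filter, and the candidate assembly at raw
p < alpha plus all on/off features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import CtMatrix, SampleSheet, ValidationError
from .normalize import ExpressionMatrix

__all__ = [
    "DetectionPartition",
    "detection_partition",
    "ModeratedTTest",
    "DEResults",
    "bh_adjust",
    "OnOffRecord",
    "onoff_lower_limit",
    "duplicate_concordance_filter",
    "assemble_candidates",
    "replicate_probe_consensus",
]

NOT_CALCULABLE = float("nan")


# ---------------------------------------------------------------------------
# detection partition and on/off bounds
# ---------------------------------------------------------------------------

@dataclass
class DetectionPartition:
    """Assay-level split into detected / low-expression-excluded / on-off."""

    detected: list[str]
    excluded: list[str]
    onoff: dict[str, str]  # assay_id -> direction
    ct_cutoff: float


def detection_partition(ct: CtMatrix, samples: SampleSheet,
                        ct_cutoff: float = 34.5) -> DetectionPartition:
    """Partition assays by detectability under the high-CT exclusion rule.

    * excluded: every sample of *both* groups is above ``ct_cutoff`` or
      undetermined (too little template to quantify anywhere);
    * on/off: undetermined in *all* samples of one group while *all*
      samples of the other group sit below the cutoff — only a fold-change
      lower bound is reportable for these;
    * detected: everything else.
    """
    if not 0 < ct_cutoff < ct.max_cycle:
        raise ValueError(f"ct_cutoff must lie in (0, {ct.max_cycle})")
    grid = ct.pivot()
    kd = grid[samples.knockdown]
    ctl = grid[samples.control]

    def _all_high(block: pd.DataFrame) -> pd.Series:
        return (block.isna() | (block > ct_cutoff)).all(axis=1)

    def _all_undet(block: pd.DataFrame) -> pd.Series:
        return block.isna().all(axis=1)

    def _all_low(block: pd.DataFrame) -> pd.Series:
        # at-the-cutoff counts as detected (exclusion is strictly above it)
        return (block.notna() & (block <= ct_cutoff)).all(axis=1)

    excluded = _all_high(kd) & _all_high(ctl)
    on_kd = _all_undet(ctl) & _all_low(kd)
    off_kd = _all_undet(kd) & _all_low(ctl)
    onoff = {}
    for assay in grid.index[(on_kd | off_kd) & ~excluded]:
        onoff[assay] = "on_in_knockdown" if on_kd[assay] else "off_in_knockdown"
    excluded_ids = grid.index[excluded].tolist()
    detected = [a for a in grid.index if a not in onoff and a not in set(excluded_ids)]
    return DetectionPartition(detected, excluded_ids, onoff, ct_cutoff)


@dataclass
class OnOffRecord:
    """Lower bound of differential expression for a feature that switches
    between detected and undetermined across the two arms; no p-value is
    calculable for such features."""

    feature_id: str
    direction: str
    log2fc_lower_limit: float
    p: float = NOT_CALCULABLE


def onoff_lower_limit(ct: CtMatrix, feature: str, samples: SampleSheet,
                      ct_cutoff: float = 34.5,
                      partition: DetectionPartition | None = None) -> OnOffRecord:
    """Lower-limit log2 fold change for an on/off feature.

    Undetermined CTs are substituted by the detection cutoff — the least
    extreme cycle compatible with non-detection — so the group-mean
    difference of ``max_cycle - CT`` is a conservative bound:
    ``limit = mean(control CT) - mean(knockdown CT)`` after substitution.
    """
    if partition is None:
        partition = detection_partition(ct, samples, ct_cutoff)
    if feature not in partition.onoff:
        raise ValidationError(f"{feature!r} is not an on/off candidate")
    grid = ct.pivot()
    kd = grid.loc[feature, samples.knockdown].to_numpy(dtype=float)
    ctl = grid.loc[feature, samples.control].to_numpy(dtype=float)
    kd = np.where(np.isnan(kd), ct_cutoff, kd)
    ctl = np.where(np.isnan(ctl), ct_cutoff, ctl)
    limit = float(ctl.mean() - kd.mean())
    return OnOffRecord(feature, partition.onoff[feature], limit)


# ---------------------------------------------------------------------------
# moderated t
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the monotone branch)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _fit_f_dist(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-match log s^2 against a scaled F to get (prior df d0, s0^2)."""
    s2 = np.maximum(s2, 1e-8)  # zero residual variance floored before log
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    n = e.size
    ebar = e.mean()
    if n < 2:
        return np.inf, float(np.exp(ebar))
    evar = np.mean((e - ebar) ** 2) * n / (n - 1) - np.mean(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0sq = np.exp(ebar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0sq = np.exp(ebar)
    return float(d0), float(s0sq)


class DEResults:
    """Per-feature moderated-t results plus the shared eBayes hyperparameters.

    Attributes
    ----------
    frame : pandas.DataFrame
        Columns ``log2fc`` (knockdown - control), ``t_mod``, ``p``, ``p_adj``
        (Benjamini-Hochberg), indexed by feature.
    prior_df, prior_var : float
        Shared d0 and s0^2 of the fitted variance prior.
    """

    def __init__(self, frame: pd.DataFrame, prior_df: float, prior_var: float,
                 n_per_group: tuple[int, int]):
        self.frame = frame
        self.prior_df = prior_df
        self.prior_var = prior_var
        self.n_per_group = n_per_group

    def __len__(self) -> int:
        return len(self.frame)

    def significant(self, alpha: float = 0.05, adjusted: bool = False) -> pd.DataFrame:
        col = "p_adj" if adjusted else "p"
        return self.frame[self.frame[col] < alpha]

    def summary(self, top: int = 10) -> str:
        n1, n2 = self.n_per_group
        lines = [
            "Moderated two-sample t (empirical-Bayes shrunken variances)",
            f"  features: {len(self.frame)}    design: {n1} knockdown vs {n2} control",
            f"  prior df d0: {self.prior_df:.4g}    prior variance s0^2: {self.prior_var:.4g}",
            f"  raw p < 0.05: {(self.frame['p'] < 0.05).sum()}"
            f"    BH p < 0.05: {(self.frame['p_adj'] < 0.05).sum()}",
            "",
            self.frame.reindex(self.frame["p"].sort_values().index)
                .head(top).to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)


class ModeratedTTest:
    """Two-group differential-expression model on a complete log2 matrix.

    Parameters
    ----------
    x : ExpressionMatrix or pandas.DataFrame
        Features x samples, no masked cells among the fitted samples.
    samples : SampleSheet
        Maps every column to knockdown or control.
    """

    def __init__(self, x: ExpressionMatrix | pd.DataFrame, samples: SampleSheet):
        values = x.values if isinstance(x, ExpressionMatrix) else x
        sample_ids = list(samples.sample_ids)
        missing = [s for s in sample_ids if s not in values.columns]
        if missing:
            raise ValidationError(f"expression matrix lacks samples {missing}")
        self.values = values[sample_ids]
        self.samples = samples
        if self.values.isna().any().any():
            raise ValidationError(
                "moderated t requires complete features; drop or mask-filter "
                "features with undetected samples first"
            )

    def fit(self, prior_df: float | None = None,
            common_variance: bool = False) -> DEResults:
        """Fit and return per-feature statistics.

        ``prior_df=None`` estimates (d0, s0^2) from the data; ``prior_df=0``
        disables shrinkage and reproduces the classical pooled two-sample t.
        ``common_variance=True`` is the fallback for designs with zero
        residual degrees of freedom (1 vs 1): every feature shares a single
        variance estimated from the spread of the fold changes.
        """
        kd = self.values[self.samples.knockdown].to_numpy(dtype=float)
        ctl = self.values[self.samples.control].to_numpy(dtype=float)
        n1, n2 = kd.shape[1], ctl.shape[1]
        d_resid = n1 + n2 - 2
        lfc = kd.mean(axis=1) - ctl.mean(axis=1)
        scale = 1.0 / n1 + 1.0 / n2

        if d_resid == 0:
            if not common_variance:
                raise ValidationError(
                    "1-vs-1 design has zero residual degrees of freedom; "
                    "refit with common_variance=True to share one variance "
                    "across all features"
                )
            # spread of fold changes across features as the common variance
            s2_common = float(np.var(lfc, ddof=1)) / scale
            se = np.sqrt(s2_common * scale)
            t = lfc / se
            p = 2.0 * stats.norm.sf(np.abs(t))
            frame = pd.DataFrame(
                {"log2fc": lfc, "t_mod": t, "p": p, "p_adj": bh_adjust(p)},
                index=self.values.index,
            )
            return DEResults(frame, np.inf, s2_common, (n1, n2))

        ss = ((kd - kd.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + \
             ((ctl - ctl.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        s2 = ss / d_resid
        df_vec = np.full(s2.shape, float(d_resid))

        if prior_df is None:
            d0, s0sq = _fit_f_dist(s2, df_vec)
        else:
            d0 = float(prior_df)
            _, s0sq = _fit_f_dist(s2, df_vec)
        if d0 == 0:
            post_var = s2
            df_total = df_vec
        elif np.isinf(d0):
            post_var = np.full_like(s2, s0sq)
            df_total = np.full_like(s2, np.inf)
        else:
            post_var = (d0 * s0sq + df_vec * s2) / (d0 + df_vec)
            df_total = d0 + df_vec
        se = np.sqrt(np.maximum(post_var, 1e-300) * scale)
        t = np.where(lfc == 0.0, 0.0, lfc / se)
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
        frame = pd.DataFrame(
            {"log2fc": lfc, "t_mod": t, "p": p, "p_adj": bh_adjust(p)},
            index=self.values.index,
        )
        return DEResults(frame, d0, s0sq, (n1, n2))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must be finite and within [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# duplicate concordance and candidate assembly
# ---------------------------------------------------------------------------

def _records_frame(de: DEResults | pd.DataFrame | None,
                   onoff: list[OnOffRecord] | None) -> pd.DataFrame:
    parts = []
    if de is not None:
        frame = de.frame if isinstance(de, DEResults) else de
        part = frame[["log2fc", "p"]].copy()
        part["p_adj"] = frame["p_adj"] if "p_adj" in frame else np.nan
        part["status"] = "tested"
        part.index.name = "feature_id"
        parts.append(part.reset_index())
    if onoff:
        part = pd.DataFrame(
            {
                "feature_id": [r.feature_id for r in onoff],
                "log2fc": [r.log2fc_lower_limit for r in onoff],
                "p": NOT_CALCULABLE,
                "p_adj": NOT_CALCULABLE,
                "status": "on_off",
                "direction": [r.direction for r in onoff],
            }
        )
        parts.append(part)
    if not parts:
        return pd.DataFrame(columns=["feature_id", "log2fc", "p", "p_adj", "status"])
    return pd.concat(parts, ignore_index=True)


def duplicate_concordance_filter(
    de: DEResults | pd.DataFrame | None,
    onoff: list[OnOffRecord] | None,
    duplicate_groups: pd.Series | dict,
) -> pd.DataFrame:
    """Apply the duplicate-assay concordance rule and collapse duplicates.

    ``duplicate_groups`` maps assay/feature id to a group key ('' or NaN for
    singletons).  Within a duplicate group, discordant signs of the fold
    change (or lower limit) remove the miRNA entirely; concordant members
    collapse to one record with the mean log2fc and the smaller p.
    """
    records = _records_frame(de, onoff)
    if records.empty:
        records["concordant"] = pd.Series(dtype=bool)
        return records
    dup = pd.Series(duplicate_groups).reindex(records["feature_id"]).fillna("")
    records = records.assign(duplicate_group=dup.to_numpy())
    singles = records[records["duplicate_group"] == ""].copy()
    singles["concordant"] = True
    collapsed = [singles]
    for key, grp in records[records["duplicate_group"] != ""].groupby("duplicate_group"):
        signs = np.sign(grp["log2fc"].to_numpy())
        if len(set(signs[signs != 0])) > 1:
            continue  # discordant replicate regulation: drop the miRNA
        rep = grp.iloc[[np.nanargmin(grp["p"].to_numpy()) if grp["p"].notna().any() else 0]].copy()
        rep["feature_id"] = key
        rep["log2fc"] = grp["log2fc"].mean()
        rep["concordant"] = True
        collapsed.append(rep)
    out = pd.concat(collapsed, ignore_index=True)
    return out.sort_values("feature_id", kind="mergesort").reset_index(drop=True)


def assemble_candidates(
    de: DEResults | pd.DataFrame | None,
    onoff: list[OnOffRecord] | None,
    alpha: float = 0.05,
    duplicate_groups: pd.Series | dict | None = None,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """Assemble the differential-expression candidate table.

    Candidates are the tested features with (raw, by default) p below
    ``alpha`` plus every on/off feature, after the duplicate-concordance
    filter; sorted by log2 fold change.  On/off rows carry no p-value.
    """
    if not 0 <= alpha < 1:
        raise ValueError(f"alpha must be in [0, 1), got {alpha}")
    if duplicate_groups is None:
        duplicate_groups = {}
    table = duplicate_concordance_filter(de, onoff, duplicate_groups)
    if table.empty:
        return table
    pcol = "p_adj" if use_adjusted else "p"
    keep = (table["status"] == "on_off") | (table[pcol] < alpha)
    out = table[keep].copy()
    out["status"] = np.where(out["status"] == "on_off", "on_off", "significant")
    out = out.sort_values("log2fc", kind="mergesort").reset_index(drop=True)
    cols = ["feature_id", "log2fc", "p", "p_adj", "status", "concordant"]
    if "direction" in out.columns:
        cols.append("direction")
    return out[cols]


# ---------------------------------------------------------------------------
# mRNA-array replicate-probe consensus
# ---------------------------------------------------------------------------

def replicate_probe_consensus(probe_de: DEResults | pd.DataFrame,
                              probe_to_gene: pd.Series | dict,
                              alpha: float = 0.05) -> pd.DataFrame:
    """Gene-level calls requiring every replicate probe to agree.

    A gene is called differentially expressed only if *all* of its probes
    are individually significant at ``alpha`` with a consistent fold-change
    sign; the gene log2fc is the mean over its probes.  Probes without a
    gene mapping are dropped with a warning.
    """
    frame = probe_de.frame if isinstance(probe_de, DEResults) else probe_de
    gene = pd.Series(probe_to_gene).reindex(frame.index)
    if gene.isna().any():
        dropped = list(frame.index[gene.isna()][:5])
        warnings.warn(f"dropping {int(gene.isna().sum())} probe(s) without a "
                      f"gene mapping (e.g. {dropped})")
    work = frame.assign(gene_id=gene).dropna(subset=["gene_id"])
    rows = []
    for g, grp in work.groupby("gene_id", sort=True):
        signs = np.sign(grp["log2fc"].to_numpy())
        called = bool((grp["p"] < alpha).all()
                      and len(set(signs[signs != 0])) <= 1
                      and (signs != 0).any())
        rows.append({
            "gene_id": g,
            "log2fc": grp["log2fc"].mean(),
            "n_probes": len(grp),
            "max_p": grp["p"].max(),
            "called": called,
        })
    return pd.DataFrame(rows).set_index("gene_id")
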