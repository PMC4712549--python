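"""Single-assay RT-qPCR quantification and cross-platform validation.

Relative quantification follows the ddCT convention: per sample,
dCT = CT(target) - mean CT(references); ddCT = dCT - mean dCT of the
calibrator group; fold change = 2^-ddCT, log2 fold change = -ddCT.
Reference candidates are ranked by total CT variance decomposed into
within-group (intra-) and between-group (inter-experimental) components.
Screen-vs-validation agreement is summarized by Spearman's rank
correlation with an exact permutation p-value at small n.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CtMatrix, SampleSheet, ValidationError

__all__ = [
    "RelativeExpression",
    "ddct_quantify",
    "reference_stability",
    "SpearmanResult",
    "spearman_validate",
]

EXACT_SPEARMAN_MAX_N = 9


@dataclass
class RelativeExpression:
    """ddCT quantification of one target in one sample."""

    target_id: str
    sample_id: str
    delta_ct: float
    ddct: float
    fold_change: float
    log2fc: float
    quantifiable: bool = True


def ddct_quantify(
    ct_target: pd.Series | dict,
    ct_refs: pd.DataFrame | pd.Series | dict,
    samples: SampleSheet,
    calibrator: str = "control",
    target_id: str = "target",
) -> pd.DataFrame:
    """Relative expression of one target against >= 1 reference genes.

    ``ct_target`` maps sample to CT; ``ct_refs`` is one Series (single
    reference) or a samples x references frame.  Multiple references are
    aggregated by the arithmetic mean of their CTs (geometric mean on the
    linear scale).  Samples with an undetermined target CT are flagged
    not-quantifiable rather than dropped.
    """
    tgt = pd.Series(ct_target, dtype=float)
    refs = pd.DataFrame(ct_refs)
    if calibrator not in ("knockdown", "control"):
        raise ValueError(f"calibrator must be a group name, got {calibrator!r}")
    sample_ids = list(samples.sample_ids)
    for s in sample_ids:
        if s not in tgt.index:
            raise ValidationError(f"missing target CT for sample {s!r}")
        if s not in refs.index or refs.loc[s].isna().any():
            raise ValidationError(f"missing reference CT for sample {s!r}")
    tgt = tgt.loc[sample_ids]
    ref_mean = refs.loc[sample_ids].mean(axis=1)
    dct = tgt - ref_mean
    calib_samples = samples.group_samples(calibrator)
    calib_dct = dct.loc[calib_samples]
    if calib_dct.isna().any():
        raise ValidationError(
            f"calibrator group {calibrator!r} contains not-quantifiable samples"
        )
    ddct = dct - calib_dct.mean()
    rows = []
    for s in sample_ids:
        ok = not math.isnan(tgt.loc[s])
        rows.append(
            {
                "target_id": target_id,
                "sample_id": s,
                "group": samples.data.set_index("sample_id").loc[s, "group"],
                "delta_ct": dct.loc[s],
                "ddct": ddct.loc[s],
                "fold_change": 2.0 ** (-ddct.loc[s]) if ok else np.nan,
                "log2fc": -ddct.loc[s],
                "quantifiable": ok,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def reference_stability(ct: CtMatrix, samples: SampleSheet) -> pd.DataFrame:
    """Rank candidate reference assays by intra- plus inter-group CT variance.

    Within-group (intra-experimental) variance is the pooled variance around
    the group means; between-group (inter-experimental) variance is the
    variance of the group means.  Candidates are ranked ascending by the
    total; ties break by assay_id.  Candidates with fewer than two numeric
    observations are excluded with a warning.
    """
    grid = ct.pivot()
    rows = []
    for assay in grid.index:
        vals = grid.loc[assay]
        if vals.notna().sum() < 2:
            warnings.warn(f"reference candidate {assay!r} has < 2 observations; excluded")
            continue
        group_vars, group_means = [], []
        for g in ("knockdown", "control"):
            gv = vals[samples.group_samples(g)].dropna()
            if len(gv) >= 2:
                group_vars.append(gv.var(ddof=1))
            if len(gv) >= 1:
                group_means.append(gv.mean())
        intra = float(np.mean(group_vars)) if group_vars else 0.0
        inter = float(np.var(group_means, ddof=1)) if len(group_means) >= 2 else 0.0
        rows.append({"assay_id": assay, "intra_var": intra, "inter_var": inter,
                     "total_var": intra + inter})
    if not rows:
        raise ValidationError("no reference candidate has enough observations")
    out = pd.DataFrame(rows).sort_values(
        ["total_var", "assay_id"], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    if len(out) == 1:
        warnings.warn("only one usable reference candidate; ranking is trivial")
    return out


@dataclass
class SpearmanResult:
    rho: float
    p: float
    n: int
    exact: bool


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    """Pearson correlation of mid-rank vectors (Spearman rho with ties)."""
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        return 0.0
    return float(rx @ ry) / denom


def spearman_validate(x, y) -> SpearmanResult:
    """Spearman correlation between two platforms' log2 fold changes.

    Mid-ranks handle ties.  The two-sided p-value is exact (full
    permutation distribution of one rank vector) for n <= 9 and uses the
    t approximation with n - 2 degrees of freedom otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("inputs must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValidationError(f"need >= 3 paired features, got {n}")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _rank_corr(rx, ry)
    if n <= EXACT_SPEARMAN_MAX_N:
        perms = np.array(list(itertools.permutations(ry)))
        rc = rx - rx.mean()
        pc = perms - perms.mean(axis=1, keepdims=True)
        denom = np.sqrt(float(rc @ rc) * (pc ** 2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            rho_perm = np.where(denom > 0, pc @ rc / denom, 0.0)
        p = float(np.mean(np.abs(rho_perm) >= abs(rho) - 1e-12))
        return SpearmanResult(rho, p, n, exact=True)
    if abs(rho) >= 1.0:
        return SpearmanResult(rho, 0.0, n, exact=False)
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return SpearmanResult(rho, float(p), n, exact=False)
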