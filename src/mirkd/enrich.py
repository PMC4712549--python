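"""Stand-alone gene-ontology enrichment over user-supplied annotations.

Per term the 2x2 overlap (k of n list genes vs K of N background genes)
is scored by the one-sided hypergeometric upper tail.  The default "ease"
method is the conservative DAVID-style variant that removes one list gene
from the overlap before computing the tail, so single-gene overlaps can
never look enriched.  The screening significance rule is fold enrichment
>= 1.5 together with raw p < 0.1; BH-adjusted p-values are reported as an
auxiliary column.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .io import ValidationError

__all__ = ["enrichment_test", "filter_enriched"]

RESULT_COLUMNS = ["term_id", "term_name", "k", "n", "K", "N",
                  "fold_enrichment", "p", "p_adj"]


def _hyper_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n)."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrichment_test(gene_list, background, gene_terms: pd.DataFrame,
                    method: str = "ease") -> pd.DataFrame:
    """Term-by-term over-representation of ``gene_list`` within ``background``.

    ``gene_terms`` has columns gene_id, term_id, term_name.  ``method``
    is "fisher" (plain hypergeometric upper tail at k) or "ease" (tail at
    max(k-1, 0)).  Fold enrichment is always (k/n)/(K/N) from the true k.
    """
    if method not in ("fisher", "ease"):
        raise ValueError(f"method must be 'fisher' or 'ease', got {method!r}")
    gene_list = set(gene_list)
    background = set(background)
    offenders = sorted(gene_list - background)
    if offenders:
        raise ValidationError(
            f"gene_list members missing from background: {offenders[:10]}"
        )
    n = len(gene_list)
    N = len(background)
    if n == 0 or N == 0:
        raise ValidationError("gene_list and background must be non-empty")
    ann = gene_terms[gene_terms["gene_id"].isin(background)]
    rows = []
    for (term_id, term_name), members in ann.groupby(["term_id", "term_name"], sort=True):
        term_genes = set(members["gene_id"])
        K = len(term_genes)
        k = len(term_genes & gene_list)
        fe = (k / n) / (K / N) if K > 0 else 0.0
        k_eff = k if method == "fisher" else max(k - 1, 0)
        p = _hyper_upper_tail(k_eff, n, K, N)
        rows.append({"term_id": term_id, "term_name": term_name,
                     "k": k, "n": n, "K": K, "N": N,
                     "fold_enrichment": fe, "p": p})
    out = pd.DataFrame(rows, columns=RESULT_COLUMNS[:-1])
    out["p_adj"] = bh_adjust(out["p"].to_numpy()) if len(out) else np.array([])
    return out.set_index("term_id")


def filter_enriched(results: pd.DataFrame, fe_min: float = 1.5,
                    p_max: float = 0.1) -> pd.DataFrame:
    """Keep terms with fold_enrichment >= fe_min and raw p < p_max.

    The fold-enrichment bound is inclusive; the p bound is strict
    (a term at exactly ``p_max`` is dropped).
    """
    if fe_min < 0:
        raise ValueError("fe_min must be >= 0")
    if not 0 < p_max <= 1:
        raise ValueError("p_max must be in (0, 1]")
    keep = (results["fold_enrichment"] >= fe_min) & (results["p"] < p_max)
    return results[keep].copy()
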