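"""CT-to-expression conversion and between-sample normalization.

Two normalizers are provided: pairwise cyclic loess on the log2 expression
scale (the standard choice for qPCR-array cards, applied separately per
plate because the two 384-well cards of one profile behave like distinct
arrays) and quantile normalization for one-color intensity arrays.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import CtMatrix, ValidationError

__all__ = ["ExpressionMatrix", "ct_to_log2", "cyclic_loess", "quantile_normalize"]


@dataclass
class ExpressionMatrix:
    """Feature x sample log2-expression grid with append-only provenance.

    NaN cells are *masked* (feature not detected in that sample), never
    imputed values.
    """

    values: pd.DataFrame
    provenance: tuple[str, ...] = field(default_factory=tuple)

    def tagged(self, tag: str) -> "ExpressionMatrix":
        """Return a copy with ``tag`` appended to the provenance trail."""
        return ExpressionMatrix(self.values.copy(), self.provenance + (tag,))

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def complete(self) -> bool:
        return not self.values.isna().any().any()


def ct_to_log2(ct: CtMatrix, max_cycle: float | None = None) -> ExpressionMatrix:
    """Convert CT cycles to log2 expression: ``value = max_cycle - ct``.

    One PCR cycle corresponds to one doubling, so the flipped cycle count is
    a log2 abundance up to an additive constant.  Undetermined wells stay
    masked (NaN).
    """
    if max_cycle is None:
        max_cycle = ct.max_cycle
    grid = ct.pivot()
    numeric_max = np.nanmax(grid.to_numpy()) if grid.notna().any().any() else 0.0
    if numeric_max > max_cycle:
        raise ValidationError(
            f"ct value {numeric_max} exceeds max_cycle {max_cycle}"
        )
    vals = max_cycle - grid
    return ExpressionMatrix(vals, (f"ct_to_log2(max_cycle={max_cycle})",))


def _loess_fit(M: np.ndarray, A: np.ndarray, span: float) -> tuple[np.ndarray, np.ndarray]:
    """Degree-1 robust loess of M on A; returns (sorted A, fitted M).

    Three robustness reweighting iterations keep genuinely differential
    features (large |M|) from dragging the normalization trend.
    """
    sm = lowess(M, A, frac=span, it=3, return_sorted=True)
    return sm[:, 0], sm[:, 1]


def cyclic_loess(
    x: ExpressionMatrix,
    plate_of: pd.Series | dict | None = None,
    *,
    span: float = 0.7,
    max_iter: int = 3,
    tol: float = 1e-3,
    min_common: int = 10,
) -> ExpressionMatrix:
    """Pairwise cyclic loess normalization, run independently per plate.

    For every unordered sample pair (i, j) within a plate, M = x_i - x_j and
    A = (x_i + x_j)/2 are formed on commonly detected features, a degree-1
    loess curve of M on A is fitted, and half the fitted trend is subtracted
    from sample i and added to sample j.  Passes over all pairs repeat until
    the largest absolute fitted trend drops below ``tol`` or ``max_iter``
    passes have run.  Features detected in only one sample of a pair do not
    enter the fit but still receive their sample's correction, evaluated at
    their own abundance.
    """
    if not 0 < span <= 1:
        raise ValueError(f"span must be in (0, 1], got {span}")
    if x.values.shape[1] < 2:
        raise ValidationError("cyclic loess needs at least 2 samples")
    vals = x.values.copy()
    if plate_of is None:
        groups = {"all": list(vals.index)}
    else:
        po = pd.Series(plate_of).reindex(vals.index)
        if po.isna().any():
            missing = list(po.index[po.isna()][:5])
            raise ValidationError(f"features without a plate assignment: {missing}")
        groups = {plate: sub.index.tolist() for plate, sub in po.groupby(po, sort=True)}
    for plate, feats in groups.items():
        block = vals.loc[feats].to_numpy(dtype=float)
        _cyclic_loess_block(block, list(vals.columns), plate,
                            span=span, max_iter=max_iter, tol=tol,
                            min_common=min_common)
        vals.loc[feats] = block
    out = ExpressionMatrix(vals, x.provenance)
    return out.tagged(
        f"cyclic_loess(span={span}, max_iter={max_iter}, tol={tol}, "
        f"plates={sorted(groups)})"
    )


def _cyclic_loess_block(block: np.ndarray, sample_names: list, plate,
                        *, span: float, max_iter: int, tol: float,
                        min_common: int) -> None:
    """In-place cyclic loess on one plate's feature x sample block."""
    n_samples = block.shape[1]
    for _ in range(max_iter):
        worst = 0.0
        # corrections for one pass are computed from a common snapshot and
        # applied together, so the result cannot depend on sample order
        correction = np.zeros_like(block)
        for i, j in itertools.combinations(range(n_samples), 2):
            xi = block[:, i]
            xj = block[:, j]
            both = np.isfinite(xi) & np.isfinite(xj)
            if both.sum() < min_common:
                raise ValidationError(
                    f"plate {plate}: samples {sample_names[i]!r} and "
                    f"{sample_names[j]!r} share only {int(both.sum())} detected "
                    f"features (< {min_common})"
                )
            M = xi[both] - xj[both]
            A = (xi[both] + xj[both]) / 2.0
            grid_a, grid_m = _loess_fit(M, A, span)
            fit = np.interp(A, grid_a, grid_m)
            correction[both, i] -= fit / 2.0
            correction[both, j] += fit / 2.0
            # half-detected features: apply the sample's correction at the
            # feature's own abundance so they remain on the normalized scale
            only_i = np.isfinite(xi) & ~np.isfinite(xj)
            if only_i.any():
                correction[only_i, i] -= np.interp(xi[only_i], grid_a, grid_m) / 2.0
            only_j = np.isfinite(xj) & ~np.isfinite(xi)
            if only_j.any():
                correction[only_j, j] += np.interp(xj[only_j], grid_a, grid_m) / 2.0
            worst = max(worst, float(np.max(np.abs(fit))))
        block += np.where(np.isfinite(block), correction, 0.0)
        if worst < tol:
            break


def quantile_normalize(x: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the across-sample mean of order statistics.

    Ranks within a sample are preserved; tied values receive the mean of the
    order-statistic replacements their tie block spans, which makes the
    transform deterministic and idempotent.
    """
    if not x.complete():
        raise ValidationError(
            "quantile normalization needs a complete matrix; filter or mask "
            "undetected features upstream"
        )
    if x.values.shape[1] < 2:
        raise ValidationError("quantile normalization needs at least 2 samples")
    v = x.values.to_numpy(dtype=float)
    n = v.shape[0]
    reference = np.sort(v, axis=0).mean(axis=1)
    out = np.empty_like(v)
    for k in range(v.shape[1]):
        col = v[:, k]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n)
        assigned[order] = reference
        # average the assigned order statistics over each tie block
        out[:, k] = pd.Series(assigned).groupby(col, sort=False).transform("mean").to_numpy()
    res = ExpressionMatrix(pd.DataFrame(out, index=x.values.index, columns=x.values.columns),
                           x.provenance)
    return res.tagged("quantile_normalize")
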