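"""SAM-style differential expression with a permutation-based FDR.

The per-gene score is a regularized two-sample t statistic

    d_i = (mean_disease_i - mean_control_i) / (se_i + s0)

where ``se_i`` is the pooled two-sample standard error and ``s0`` a small
fudge constant that damps the scores of genes with tiny variance ("auto"
sets it to the median of the pooled standard errors).  q-values come from a
label-permutation null: for each threshold c on |d| the false discovery rate
is estimated as the median permutation count of |d*| >= c divided by the
observed count, and a gene's q-value is the minimum estimated FDR over the
rejection regions that contain it.  When the requested number of
permutations meets or exceeds the number of distinct label assignments the
null is enumerated exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, GeneSet, SampleGroups

__all__ = ["DEResult", "sam_statistic", "permutation_fdr", "select_de"]


@dataclass
class DEResult:
    """Per-gene d statistic, pooled standard error, q-value and selection flag."""

    table: pd.DataFrame  # index gene; columns d_statistic, pooled_se, q_value, selected
    s0: float
    n_perm: int = 0
    exact: bool = False

    def selected_genes(self) -> GeneSet:
        sel = self.table.index[self.table["selected"]]
        return GeneSet("de_genes", frozenset(sel))


def _group_masks(
    expr: ExpressionMatrix, groups: SampleGroups
) -> tuple[np.ndarray, np.ndarray]:
    groups.validate_against(expr)
    cols = expr.sample_ids
    d_mask = np.array([groups.labels[s] == "disease" for s in cols])
    c_mask = ~d_mask
    if d_mask.sum() < 2 or c_mask.sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    return d_mask, c_mask


def _d_and_se(
    X: np.ndarray, d_mask: np.ndarray, c_mask: np.ndarray, s0: float
) -> tuple[np.ndarray, np.ndarray]:
    n1, n2 = int(d_mask.sum()), int(c_mask.sum())
    xd, xc = X[:, d_mask], X[:, c_mask]
    diff = xd.mean(axis=1) - xc.mean(axis=1)
    v1 = xd.var(axis=1, ddof=1)
    v2 = xc.var(axis=1, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        d = diff / (se + s0)
    d[np.isnan(d)] = 0.0  # 0/0: identical, constant groups
    return d, se


def _resolve_s0(se: np.ndarray, s0: float | str) -> float:
    if isinstance(s0, str):
        if s0 != "auto":
            raise ValueError("s0 must be a non-negative number or 'auto'")
        return float(np.median(se))
    if s0 < 0:
        raise ValueError("s0 must be >= 0")
    return float(s0)


def sam_statistic(
    expr: ExpressionMatrix, groups: SampleGroups, s0: float | str = "auto"
) -> DEResult:
    """Compute the regularized d statistic for every gene (no q-values)."""
    d_mask, c_mask = _group_masks(expr, groups)
    X = expr.values.to_numpy(dtype=float)
    _, se = _d_and_se(X, d_mask, c_mask, 0.0)
    s0_val = _resolve_s0(se, s0)
    d, se = _d_and_se(X, d_mask, c_mask, s0_val)
    table = pd.DataFrame(
        {
            "d_statistic": d,
            "pooled_se": se,
            "q_value": np.nan,
            "selected": False,
        },
        index=expr.values.index,
    )
    return DEResult(table, s0=s0_val)


def _null_masks(
    n: int, n_disease: int, n_perm: int, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """Boolean disease-masks for the permutation null; exact when feasible."""
    total = comb(n, n_disease)
    if n_perm >= total:
        masks = np.zeros((total, n), dtype=bool)
        for i, idx in enumerate(combinations(range(n), n_disease)):
            masks[i, list(idx)] = True
        return masks, True
    masks = np.zeros((n_perm, n), dtype=bool)
    for i in range(n_perm):
        masks[i, rng.choice(n, size=n_disease, replace=False)] = True
    return masks, False


def permutation_fdr(
    expr: ExpressionMatrix,
    groups: SampleGroups,
    n_perm: int = 100,
    seed: int | None = None,
    s0: float | str = "auto",
) -> DEResult:
    """d statistics plus permutation-estimated q-values.

    For each candidate threshold c (the observed |d| values),
    FDR(c) = median_b #{|d*_b| >= c} / #{|d| >= c}, clipped to [0, 1];
    q_i = min over thresholds c <= |d_i| of FDR(c).  The minimum over nested
    rejection regions makes q monotone non-increasing in |d|.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    result = sam_statistic(expr, groups, s0=s0)
    d_mask, c_mask = _group_masks(expr, groups)
    X = expr.values.to_numpy(dtype=float)
    abs_d = np.abs(result.table["d_statistic"].to_numpy())

    rng = np.random.default_rng(seed)
    masks, exact = _null_masks(X.shape[1], int(d_mask.sum()), n_perm, rng)
    null_abs = np.empty((masks.shape[0], X.shape[0]))
    for b, m in enumerate(masks):
        db, _ = _d_and_se(X, m, ~m, result.s0)
        null_abs[b] = np.abs(db)

    # thresholds ascending; counts via sorted search
    thresholds = np.unique(abs_d)
    obs_sorted = np.sort(abs_d)
    n_obs = len(abs_d) - np.searchsorted(obs_sorted, thresholds, side="left")
    null_sorted = np.sort(null_abs, axis=1)
    n_null = len(abs_d) - np.array(
        [np.searchsorted(row, thresholds, side="left") for row in null_sorted]
    )
    fdr = np.median(n_null, axis=0) / np.maximum(n_obs, 1)
    fdr = np.minimum(fdr, 1.0)
    # q at threshold k = min FDR over thresholds <= k (regions containing the gene)
    q_at = np.minimum.accumulate(fdr)
    idx = np.searchsorted(thresholds, abs_d, side="right") - 1
    q = q_at[idx]

    table = result.table.copy()
    table["q_value"] = q
    return DEResult(table, s0=result.s0, n_perm=masks.shape[0], exact=exact)


def select_de(
    result: DEResult, fdr_threshold: float = 0.98, direction: str = "positive"
) -> GeneSet:
    """Select genes with q <= threshold and the requested sign of d."""
    if not 0.0 < fdr_threshold <= 1.0:
        raise ValueError("fdr_threshold must be in (0, 1]")
    if direction not in ("positive", "negative", "both"):
        raise ValueError("direction must be positive, negative or both")
    q = result.table["q_value"]
    d = result.table["d_statistic"]
    mask = q <= fdr_threshold
    if direction == "positive":
        mask &= d > 0
    elif direction == "negative":
        mask &= d < 0
    result.table["selected"] = mask
    return GeneSet("de_genes", frozenset(result.table.index[mask]))
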