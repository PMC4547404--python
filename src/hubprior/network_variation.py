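"""Differential co-expression of hubs: the AvgPCC permutation test.

For a hub with n usable interactors, AvgPCC = mean_i (D_i - C_i) where D_i
and C_i are the Pearson correlations of the hub with interactor i over the
disease and control samples respectively.  Significance comes from a
sample-label permutation null (group sizes preserved, network topology
untouched): AvgPCC is recomputed under random labelings (RandomPCC), the
default two-sided p-value is the fraction of |RandomPCC| >= |AvgPCC|, and
p-values are Bonferroni-corrected over the hubs actually tested.

A hub's usable interactors are those whose expression is non-constant in
both groups under the observed labelling; hubs with no usable interactor
(or a constant profile themselves) are excluded with a recorded reason
rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, GeneSet, SampleGroups
from .network_topology import InteractionNetwork

__all__ = [
    "NetVarResult",
    "hub_avg_pcc",
    "permutation_null",
    "hub_pvalues",
    "network_variation",
]


@dataclass
class NetVarResult:
    """Observed AvgPCC, permutation null and (after `hub_pvalues`) p-values."""

    table: pd.DataFrame  # index hub_id; n_interactors, avg_pcc, p_value,
    #                      p_adjusted, significant
    null: np.ndarray  # (n_perm, n_hubs) RandomPCC values
    excluded: dict[str, str] = field(default_factory=dict)
    n_perm: int = 0
    exact: bool = False
    sidedness: str | None = None
    alpha: float | None = None

    def significant_hubs(self) -> GeneSet:
        sel = self.table.index[self.table["significant"].fillna(False)]
        return GeneSet("netvar_hubs", frozenset(sel))


def _pair_corr(
    X: np.ndarray, cols: np.ndarray, h_idx: np.ndarray, i_idx: np.ndarray
) -> np.ndarray:
    """Pearson correlation of row pairs (h, i) over the given columns.

    Pairs where either profile is constant yield NaN.
    """
    sub = X[:, cols]
    centered = sub - sub.mean(axis=1, keepdims=True)
    ss = (centered**2).sum(axis=1)
    num = (centered[h_idx] * centered[i_idx]).sum(axis=1)
    den = np.sqrt(ss[h_idx] * ss[i_idx])
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return r


@dataclass
class _Prepared:
    X: np.ndarray
    hubs: list[str]
    h_idx: np.ndarray  # per pair, hub row
    i_idx: np.ndarray  # per pair, interactor row
    bounds: np.ndarray  # hub h owns pairs bounds[h]:bounds[h+1]
    d_cols: np.ndarray
    c_cols: np.ndarray
    excluded: dict[str, str]


def _prepare(
    expr: ExpressionMatrix,
    groups: SampleGroups,
    net: InteractionNetwork,
    hubs: list[str] | GeneSet,
) -> _Prepared:
    groups.validate_against(expr)
    samples = expr.sample_ids
    d_cols = np.array([i for i, s in enumerate(samples) if groups.labels[s] == "disease"])
    c_cols = np.array([i for i, s in enumerate(samples) if groups.labels[s] == "control"])
    if len(d_cols) < 3 or len(c_cols) < 3:
        raise ValueError("each group needs at least 3 samples for correlations")
    X = expr.values.to_numpy(dtype=float)
    row_of = {g: i for i, g in enumerate(expr.gene_ids)}

    def _varies(row: int) -> bool:
        return X[row, d_cols].std() > 0 and X[row, c_cols].std() > 0

    kept_hubs: list[str] = []
    excluded: dict[str, str] = {}
    h_idx: list[int] = []
    i_idx: list[int] = []
    bounds = [0]
    for hub in sorted(set(hubs if isinstance(hubs, GeneSet) else hubs)):
        if hub not in row_of:
            excluded[hub] = "absent from expression matrix"
            continue
        if hub not in net:
            excluded[hub] = "absent from network"
            continue
        if not _varies(row_of[hub]):
            excluded[hub] = "constant expression profile"
            continue
        usable = [
            row_of[n]
            for n in sorted(net.neighbors(hub))
            if n in row_of and _varies(row_of[n])
        ]
        if not usable:
            excluded[hub] = "no usable interactor"
            continue
        kept_hubs.append(hub)
        h_idx.extend([row_of[hub]] * len(usable))
        i_idx.extend(usable)
        bounds.append(bounds[-1] + len(usable))
    return _Prepared(
        X=X,
        hubs=kept_hubs,
        h_idx=np.array(h_idx, dtype=int),
        i_idx=np.array(i_idx, dtype=int),
        bounds=np.array(bounds, dtype=int),
        d_cols=d_cols,
        c_cols=c_cols,
        excluded=excluded,
    )


def _avg_pcc_for_cols(
    prep: _Prepared, d_cols: np.ndarray, c_cols: np.ndarray
) -> np.ndarray:
    d = _pair_corr(prep.X, d_cols, prep.h_idx, prep.i_idx)
    c = _pair_corr(prep.X, c_cols, prep.h_idx, prep.i_idx)
    diff = d - c
    out = np.empty(len(prep.hubs))
    for k in range(len(prep.hubs)):
        seg = diff[prep.bounds[k] : prep.bounds[k + 1]]
        with np.errstate(invalid="ignore"):
            out[k] = np.nanmean(seg) if np.isfinite(seg).any() else np.nan
    return out


def hub_avg_pcc(
    expr: ExpressionMatrix,
    groups: SampleGroups,
    net: InteractionNetwork,
    hub: str,
) -> tuple[float, int]:
    """Observed AvgPCC and usable-interactor count for one hub."""
    prep = _prepare(expr, groups, net, [hub])
    if hub in prep.excluded:
        raise ValueError(f"hub {hub!r} excluded: {prep.excluded[hub]}")
    avg = _avg_pcc_for_cols(prep, prep.d_cols, prep.c_cols)[0]
    return float(avg), int(prep.bounds[1] - prep.bounds[0])


def permutation_null(
    expr: ExpressionMatrix,
    groups: SampleGroups,
    net: InteractionNetwork,
    hubs: list[str] | GeneSet,
    n_perm: int = 1000,
    seed: int | None = None,
    masks: np.ndarray | None = None,
) -> NetVarResult:
    """Observed AvgPCC per hub plus the RandomPCC permutation null.

    Each permutation reassigns sample labels at random, preserving group
    sizes, and recomputes AvgPCC for every hub on the untouched topology.
    When the number of distinct label splits does not exceed *n_perm* the
    null is the exact enumeration of all splits.  *masks* (boolean
    permutation × sample array marking the disease group) overrides the
    random stream and is intended for testing.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    prep = _prepare(expr, groups, net, hubs)
    observed = _avg_pcc_for_cols(prep, prep.d_cols, prep.c_cols)
    n_samples = prep.X.shape[1]
    n_d = len(prep.d_cols)

    exact = False
    if masks is None:
        total = comb(n_samples, n_d)
        if n_perm >= total:
            masks = np.zeros((total, n_samples), dtype=bool)
            for i, idx in enumerate(combinations(range(n_samples), n_d)):
                masks[i, list(idx)] = True
            exact = True
        else:
            rng = np.random.default_rng(seed)
            masks = np.zeros((n_perm, n_samples), dtype=bool)
            for i in range(n_perm):
                masks[i, rng.choice(n_samples, size=n_d, replace=False)] = True

    null = np.empty((masks.shape[0], len(prep.hubs)))
    all_cols = np.arange(n_samples)
    for b, m in enumerate(masks):
        null[b] = _avg_pcc_for_cols(prep, all_cols[m], all_cols[~m])

    n_int = np.diff(prep.bounds)
    table = pd.DataFrame(
        {
            "n_interactors": n_int.astype(int),
            "avg_pcc": observed,
            "p_value": np.nan,
            "p_adjusted": np.nan,
            "significant": pd.array([pd.NA] * len(prep.hubs), dtype="boolean"),
        },
        index=pd.Index(prep.hubs, name="hub_id"),
    )
    return NetVarResult(
        table, null=null, excluded=prep.excluded, n_perm=masks.shape[0], exact=exact
    )


def hub_pvalues(
    result: NetVarResult,
    alpha: float = 0.05,
    sidedness: str = "two_sided",
    smooth: bool = False,
) -> NetVarResult:
    """Permutation p-values with Bonferroni correction.

    ``two_sided`` (default): p = #{|RandomPCC| >= |AvgPCC|} / n_perm.
    ``paper_literal``: p = #{AvgPCC >= RandomPCC} / n_perm, the printed
    one-sided estimator (which approaches 1, not 0, for strong effects).
    With *smooth*, p = (1 + b) / (1 + n_perm) to avoid exact zeros.
    The Bonferroni divisor is the number of hubs actually tested.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if sidedness not in ("two_sided", "paper_literal"):
        raise ValueError("sidedness must be 'two_sided' or 'paper_literal'")
    obs = result.table["avg_pcc"].to_numpy()
    n_perm = result.null.shape[0]
    if sidedness == "two_sided":
        b = (np.abs(result.null) >= np.abs(obs)[None, :]).sum(axis=0)
    else:
        b = (obs[None, :] >= result.null).sum(axis=0)
    p = (1.0 + b) / (1.0 + n_perm) if smooth else b / n_perm
    n_tested = len(result.table)
    p_adj = np.minimum(1.0, p * n_tested)
    table = result.table.copy()
    table["p_value"] = p
    table["p_adjusted"] = p_adj
    table["significant"] = pd.array(p_adj <= alpha, dtype="boolean")
    return NetVarResult(
        table,
        null=result.null,
        excluded=result.excluded,
        n_perm=n_perm,
        exact=result.exact,
        sidedness=sidedness,
        alpha=alpha,
    )


def network_variation(
    expr: ExpressionMatrix,
    groups: SampleGroups,
    net: InteractionNetwork,
    hubs: list[str] | GeneSet,
    n_perm: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
    sidedness: str = "two_sided",
    smooth: bool = False,
) -> NetVarResult:
    """Convenience wrapper: null construction followed by p-value assignment."""
    result = permutation_null(expr, groups, net, hubs, n_perm=n_perm, seed=seed)
    return hub_pvalues(result, alpha=alpha, sidedness=sidedness, smooth=smooth)
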