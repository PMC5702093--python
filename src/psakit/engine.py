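"""Variance-reduction tree derivation engine.

Reimplements the derivation method used to build the Personal Support
Algorithm: recursive partitioning of a continuous target (weekly hours of
personal support) on ordinal assessment variables, with

* one-way ANOVA F-tests (variance reduction) as the splitting criterion,
* Bonferroni adjustment over every candidate partition evaluated at a node,
* binary splits preferred, contiguous multi-way splits optional,
* a depth cap (default six levels) and a minimum terminal-node size
  (default 100 observations),
* interactive growth via a forced first variable and per-node overrides, and
* collapsing of terminal nodes into ordered groups by dynamic-programming
  1-D clustering of the leaf means.

The Bonferroni multiplicity ``m`` is the total number of admissible
partitions evaluated at the node across all candidate variables, so the
probability of any false split at a pure-noise node is controlled at the
significance level; the per-variable count is retained on the returned
candidate for inspection.

A scikit-learn estimator facade (:class:`HoursTreeRegressor`) wraps the
functional API so derived trees compose with sklearn model selection; its
``predict`` returns the leaf mean, hence ``score`` is the explained variance
of the partition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .errors import ConfigurationError
from .tree import LeafNode, SplitNode, TreeSpec

__all__ = [
    "GrowthParams",
    "SplitCandidate",
    "one_way_f",
    "bonferroni",
    "best_split",
    "grow_tree",
    "collapse_leaves",
    "cluster_leaf_means",
    "derivation_validation_split",
    "HoursTreeRegressor",
]


@dataclass(frozen=True)
class GrowthParams:
    """Tree-growth controls mirroring the published derivation parameters."""

    max_depth: int = 6
    min_leaf: int = 100
    alpha: float = 0.05
    allow_multiway: bool = True
    max_way: int = 3
    forced_first_variable: Optional[str] = None
    random_seed: Optional[int] = None

    def __post_init__(self):
        if self.max_depth < 1:
            raise ConfigurationError("max_depth must be >= 1")
        if self.min_leaf < 1:
            raise ConfigurationError("min_leaf must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.max_way < 2:
            raise ConfigurationError("max_way must be >= 2")


@dataclass(frozen=True)
class SplitCandidate:
    """A scored candidate partition of one node."""

    variable: str
    cuts: tuple[float, ...]
    arity: int
    f_stat: float
    p_raw: float
    p_adj: float
    m: int           # partitions evaluated at the node (all variables)
    m_variable: int  # partitions evaluated for this variable


def one_way_f(values, labels) -> tuple[float, float]:
    """One-way ANOVA F statistic and upper-tail p for a partition.

    ``labels`` assigns each observation to a group.  Zero total variance is
    defined as (F=0, p=1); zero within-group variance with non-zero
    between-group variance gives (inf, 0).
    """
    y = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    if y.shape != lab.shape:
        raise ConfigurationError("values and labels must align")
    groups, inv = np.unique(lab, return_inverse=True)
    k = len(groups)
    n = len(y)
    if k < 2:
        raise ConfigurationError("need at least 2 non-empty groups")
    if n <= k:
        raise ConfigurationError("need more observations than groups")
    counts = np.bincount(inv)
    sums = np.bincount(inv, weights=y)
    means = sums / counts
    grand = y.mean()
    ssb = float(np.sum(counts * (means - grand) ** 2))
    sst = float(np.sum((y - grand) ** 2))
    ssw = max(sst - ssb, 0.0)
    if sst <= 1e-12 * max(1.0, abs(grand)):
        return 0.0, 1.0
    dfb, dfw = k - 1, n - k
    if ssw <= 1e-12 * sst:
        return float("inf"), 0.0
    f_stat = (ssb / dfb) / (ssw / dfw)
    return f_stat, float(stats.f.sf(f_stat, dfb, dfw))


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value: min(1, m * p)."""
    if not 0 <= p <= 1:
        raise ConfigurationError(f"p must be in [0, 1], got {p}")
    if m < 1:
        raise ConfigurationError(f"m must be >= 1, got {m}")
    return min(1.0, m * p)


def _admissible_partitions(
    counts: np.ndarray, min_leaf: int, allow_multiway: bool, max_way: int
) -> list[tuple[int, ...]]:
    """Contiguous partitions of the ordered levels with every part >= min_leaf.

    Each partition is a tuple of boundary indices b; part j spans levels
    (b_{j-1}, b_j].  Binary partitions come first (preferred arity).
    """
    c = len(counts)
    cum = np.concatenate([[0], np.cumsum(counts)])
    n = cum[-1]
    parts: list[tuple[int, ...]] = []
    for b in range(1, c):
        if cum[b] >= min_leaf and n - cum[b] >= min_leaf:
            parts.append((b,))
    if allow_multiway:
        for way in range(3, max_way + 1):
            for bs in combinations(range(1, c), way - 1):
                bounds = (0, *bs, c)
                sizes = [cum[bounds[i + 1]] - cum[bounds[i]] for i in range(way)]
                if min(sizes) >= min_leaf:
                    parts.append(bs)
    return parts


def _partition_f(
    counts: np.ndarray, sums: np.ndarray, sumsq: np.ndarray, bounds: tuple[int, ...]
) -> tuple[float, float]:
    """F and p for one contiguous partition from per-level sufficient stats."""
    cum_n = np.concatenate([[0], np.cumsum(counts)])
    cum_s = np.concatenate([[0.0], np.cumsum(sums)])
    cum_q = np.concatenate([[0.0], np.cumsum(sumsq)])
    edges = (0, *bounds, len(counts))
    ns = np.diff(cum_n[list(edges)])
    ss = np.diff(cum_s[list(edges)])
    qs = np.diff(cum_q[list(edges)])
    n = int(ns.sum())
    k = len(ns)
    grand = ss.sum() / n
    sst = float(qs.sum() - n * grand**2)
    ssb = float(np.sum(ss**2 / ns) - n * grand**2)
    ssb = max(ssb, 0.0)
    ssw = max(sst - ssb, 0.0)
    if sst <= 1e-12 * max(1.0, grand**2 * n):
        return 0.0, 1.0
    dfb, dfw = k - 1, n - k
    if dfw <= 0:
        return 0.0, 1.0
    if ssw <= 1e-12 * sst:
        return float("inf"), 0.0
    f_stat = (ssb / dfb) / (ssw / dfw)
    return f_stat, float(stats.f.sf(f_stat, dfb, dfw))


def best_split(
    X: pd.DataFrame,
    y,
    params: GrowthParams | None = None,
    candidate_vars: Sequence[str] | None = None,
    require_significant: bool = True,
) -> Optional[SplitCandidate]:
    """Best admissible partition of a node, or None.

    Evaluates every admissible contiguous partition of every candidate
    variable, Bonferroni-adjusts over the total number evaluated, and returns
    the partition minimising the adjusted p-value provided it clears the
    significance level (``require_significant=False`` skips the gate and
    reports the best candidate regardless, for interactive exploration).
    Ties are broken by larger F, then binary before multi-way, then smaller
    cut values, then variable name.
    """
    params = params or GrowthParams()
    y = np.asarray(y, dtype=float)
    if len(X) != len(y):
        raise ConfigurationError("X and y must align")
    if len(y) < 2 * params.min_leaf:
        return None
    variables = list(candidate_vars) if candidate_vars is not None else list(X.columns)
    missing_vars = [v for v in variables if v not in X.columns]
    if missing_vars:
        raise ConfigurationError(f"candidate variable not in data: {missing_vars[0]}")

    scored: list[tuple[tuple, SplitCandidate]] = []
    m_total = 0
    per_var: list[tuple[str, list, np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = []
    for var in variables:
        x = pd.to_numeric(X[var], errors="coerce").to_numpy(dtype=float)
        mask = ~np.isnan(x)
        if mask.sum() < 2 * params.min_leaf:
            continue
        xv, yv = x[mask], y[mask]
        levels, inv = np.unique(xv, return_inverse=True)
        if len(levels) < 2:
            continue
        counts = np.bincount(inv)
        sums = np.bincount(inv, weights=yv)
        sumsq = np.bincount(inv, weights=yv**2)
        parts = _admissible_partitions(
            counts, params.min_leaf, params.allow_multiway, params.max_way
        )
        m_total += len(parts)
        per_var.append((var, parts, levels, counts, sums, sumsq))

    if m_total == 0:
        return None

    for var, parts, levels, counts, sums, sumsq in per_var:
        m_variable = len(parts)
        for bounds in parts:
            f_stat, p_raw = _partition_f(counts, sums, sumsq, bounds)
            cuts = tuple(float(levels[b]) for b in bounds)
            cand = SplitCandidate(
                variable=var,
                cuts=cuts,
                arity=len(bounds) + 1,
                f_stat=f_stat,
                p_raw=p_raw,
                p_adj=bonferroni(p_raw, m_total),
                m=m_total,
                m_variable=m_variable,
            )
            key = (p_raw, -f_stat, cand.arity, cuts, var)
            scored.append((key, cand))

    best = min(scored, key=lambda t: t[0])[1]
    if require_significant and best.p_adj >= params.alpha:
        return None
    return best


# ---------------------------------------------------------------------------
# growth
# ---------------------------------------------------------------------------

def grow_tree(
    X: pd.DataFrame,
    y,
    params: GrowthParams | None = None,
    overrides: Mapping[str, str] | None = None,
    version: str = "derived",
) -> TreeSpec:
    """Grow a tree by recursive partitioning; terminals carry n and mean.

    ``overrides`` maps a node path (child indices joined to a string, "" for
    the root) to a variable the split at that node must use — the interactive
    growth mode.  ``params.forced_first_variable`` is shorthand for an
    override at the root.  Terminal groups are unset until
    :func:`collapse_leaves`.
    """
    params = params or GrowthParams()
    overrides = dict(overrides or {})
    if params.forced_first_variable is not None:
        overrides.setdefault("", params.forced_first_variable)
    for path, var in overrides.items():
        if var not in X.columns:
            raise ConfigurationError(
                f"override variable {var!r} (path {path!r}) not in data"
            )
    y = np.asarray(y, dtype=float)
    if len(y) == 0:
        raise ConfigurationError("cannot grow a tree on empty data")

    nodes: dict[str, SplitNode | LeafNode] = {}
    counter = [0]

    def new_id() -> str:
        counter[0] += 1
        return f"n{counter[0]}"

    def build(idx: np.ndarray, depth: int, path: str) -> str:
        nid = new_id()
        yv = y[idx]
        cand = None
        if depth < params.max_depth and len(idx) >= 2 * params.min_leaf:
            restrict = [overrides[path]] if path in overrides else None
            cand = best_split(X.iloc[idx], yv, params, candidate_vars=restrict)
        if cand is None:
            nodes[nid] = LeafNode(nid, group=None, n=len(idx), mean=float(yv.mean()))
            return nid
        x = pd.to_numeric(X[cand.variable], errors="coerce").to_numpy(dtype=float)[idx]
        edges = (-np.inf, *cand.cuts, np.inf)
        children = []
        for j in range(len(edges) - 1):
            sub = idx[(x >= edges[j]) & (x < edges[j + 1])]
            children.append(build(sub, depth + 1, path + str(j)))
        nodes[nid] = SplitNode(nid, cand.variable, cand.cuts, tuple(children))
        return nid

    all_idx = np.arange(len(y))
    root_id = build(all_idx, 0, "")
    feature_ranges = {
        c: [float(np.nanmin(pd.to_numeric(X[c], errors="coerce"))),
            float(np.nanmax(pd.to_numeric(X[c], errors="coerce")))]
        for c in X.columns
    }
    return TreeSpec(
        root_id=root_id,
        nodes=nodes,
        version=version,
        metadata={
            "engine": "psakit",
            "params": {
                "max_depth": params.max_depth,
                "min_leaf": params.min_leaf,
                "alpha": params.alpha,
                "allow_multiway": params.allow_multiway,
                "max_way": params.max_way,
                "forced_first_variable": params.forced_first_variable,
            },
            "n": int(len(y)),
            "feature_ranges": feature_ranges,
        },
    )


# ---------------------------------------------------------------------------
# leaf collapsing
# ---------------------------------------------------------------------------

def cluster_leaf_means(
    means: Sequence[float], weights: Sequence[float], k: int
) -> list[int]:
    """Optimal contiguous k-grouping of sorted means minimising weighted SSE.

    Input means must be sorted ascending; returns a 0-based group index per
    mean (dynamic programme, the reproducible stand-in for the manual
    merge-by-similar-averages step).
    """
    m = np.asarray(means, dtype=float)
    w = np.asarray(weights, dtype=float)
    L = len(m)
    if k < 1 or k > L:
        raise ConfigurationError(f"k must be in [1, {L}], got {k}")
    if np.any(np.diff(m) < 0):
        raise ConfigurationError("means must be sorted ascending")
    cw = np.concatenate([[0.0], np.cumsum(w)])
    cwm = np.concatenate([[0.0], np.cumsum(w * m)])
    cwm2 = np.concatenate([[0.0], np.cumsum(w * m**2)])

    def cost(i: int, j: int) -> float:  # block [i, j) of sorted means
        wt = cw[j] - cw[i]
        s = cwm[j] - cwm[i]
        q = cwm2[j] - cwm2[i]
        return max(q - s * s / wt, 0.0)

    INF = float("inf")
    dp = np.full((k + 1, L + 1), INF)
    back = np.zeros((k + 1, L + 1), dtype=int)
    dp[0, 0] = 0.0
    for g in range(1, k + 1):
        for j in range(g, L + 1):
            for i in range(g - 1, j):
                c = dp[g - 1, i] + cost(i, j)
                if c < dp[g, j] - 1e-15:
                    dp[g, j] = c
                    back[g, j] = i
    labels = np.zeros(L, dtype=int)
    j = L
    for g in range(k, 0, -1):
        i = back[g, j]
        labels[i:j] = g - 1
        j = i
    return labels.tolist()


def collapse_leaves(
    tree: TreeSpec,
    k: int,
    X: pd.DataFrame | None = None,
    y=None,
) -> TreeSpec:
    """Collapse terminal nodes into k ordered groups by similar leaf means.

    Leaf means/sizes are taken from the stored leaf statistics, or recomputed
    from (X, y) when given.  Groups are labelled "1"..."k" in increasing order
    of mean; the resulting group means are strictly increasing (an exact tie
    forced apart by too large a k raises ConfigurationError).
    """
    leaves = tree.leaves
    if not leaves:
        raise ConfigurationError("tree has no terminal nodes")
    if k > len(leaves):
        raise ConfigurationError(
            f"requested {k} groups but tree has {len(leaves)} terminal nodes"
        )
    if X is not None:
        y = np.asarray(y, dtype=float)
        stats_: dict[str, tuple[int, float]] = {}
        leaf_ids = _route_frame(tree, X)
        for lid in (lf.node_id for lf in leaves):
            sel = y[leaf_ids == lid]
            if len(sel) == 0:
                raise ConfigurationError(f"leaf {lid!r} receives no data")
            stats_[lid] = (len(sel), float(sel.mean()))
    else:
        if any(lf.n is None or lf.mean is None for lf in leaves):
            raise ConfigurationError("leaves carry no stored statistics; pass X, y")
        stats_ = {lf.node_id: (lf.n, lf.mean) for lf in leaves}

    order = sorted(stats_, key=lambda lid: stats_[lid][1])
    means = [stats_[lid][1] for lid in order]
    weights = [stats_[lid][0] for lid in order]
    labels = cluster_leaf_means(means, weights, k)

    group_means = []
    for g in range(k):
        idx = [i for i, lab in enumerate(labels) if lab == g]
        wt = sum(weights[i] for i in idx)
        group_means.append(sum(weights[i] * means[i] for i in idx) / wt)
    if any(b <= a for a, b in zip(group_means, group_means[1:])):
        raise ConfigurationError(
            "collapse produced non-increasing group means; reduce k "
            "(tied leaf means cannot be split across groups)"
        )

    mapping = {lid: str(labels[i] + 1) for i, lid in enumerate(order)}
    nodes: dict[str, SplitNode | LeafNode] = {}
    for nid, node in tree.nodes.items():
        if isinstance(node, LeafNode):
            nodes[nid] = replace(node, group=mapping[nid])
        else:
            nodes[nid] = node
    metadata = dict(tree.metadata)
    metadata["group_means"] = group_means
    return TreeSpec(tree.root_id, nodes, version=tree.version, metadata=metadata)


def _route_frame(tree: TreeSpec, X: pd.DataFrame) -> np.ndarray:
    """Terminal node id per row of a feature frame."""
    out = np.empty(len(X), dtype=object)
    cols = {c: pd.to_numeric(X[c], errors="coerce").to_numpy(dtype=float) for c in X.columns}
    for i in range(len(X)):
        feats = {c: cols[c][i] for c in cols}
        out[i] = tree.route(feats)
    return out


def derivation_validation_split(
    df: pd.DataFrame, frac: float = 0.7, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded random partition into derivation (frac) and validation rows."""
    if not 0 < frac < 1:
        raise ConfigurationError("frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(df))
    n_der = int(round(frac * len(df)))
    return df.iloc[perm[:n_der]].copy(), df.iloc[perm[n_der:]].copy()


# ---------------------------------------------------------------------------
# sklearn facade
# ---------------------------------------------------------------------------

class HoursTreeRegressor(BaseEstimator, RegressorMixin):
    """Recursive-partitioning regressor with F-test/Bonferroni splitting.

    Parameters mirror :class:`GrowthParams`.  ``fit`` grows the tree on a
    feature DataFrame and a continuous target; ``predict`` returns the mean
    of the terminal node each row routes to, so ``score`` is the partition's
    explained variance.  The fitted tree is available as ``tree_spec_`` and
    can be collapsed into ordered groups with :meth:`collapse`.
    """

    def __init__(
        self,
        max_depth: int = 6,
        min_leaf: int = 100,
        alpha: float = 0.05,
        allow_multiway: bool = True,
        max_way: int = 3,
        forced_first_variable: Optional[str] = None,
        random_state: Optional[int] = None,
    ):
        self.max_depth = max_depth
        self.min_leaf = min_leaf
        self.alpha = alpha
        self.allow_multiway = allow_multiway
        self.max_way = max_way
        self.forced_first_variable = forced_first_variable
        self.random_state = random_state

    def _params(self) -> GrowthParams:
        return GrowthParams(
            max_depth=self.max_depth,
            min_leaf=self.min_leaf,
            alpha=self.alpha,
            allow_multiway=self.allow_multiway,
            max_way=self.max_way,
            forced_first_variable=self.forced_first_variable,
            random_seed=self.random_state,
        )

    @staticmethod
    def _frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X)
        return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])

    def fit(self, X, y, overrides: Mapping[str, str] | None = None):
        frame = self._frame(X)
        self.feature_names_in_ = np.asarray(frame.columns, dtype=object)
        self.n_features_in_ = frame.shape[1]
        self.tree_spec_ = grow_tree(frame, y, self._params(), overrides=overrides)
        self.n_leaves_ = len(self.tree_spec_.leaves)
        self.leaf_means_ = {
            lf.node_id: lf.mean for lf in self.tree_spec_.leaves
        }
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "tree_spec_")
        frame = self._frame(X)
        leaf_ids = _route_frame(self.tree_spec_, frame)
        return np.array([self.leaf_means_[lid] for lid in leaf_ids])

    def apply(self, X) -> np.ndarray:
        """Terminal node id per row (sklearn's ``apply`` convention)."""
        check_is_fitted(self, "tree_spec_")
        return _route_frame(self.tree_spec_, self._frame(X))

    def collapse(self, k: int) -> TreeSpec:
        check_is_fitted(self, "tree_spec_")
        return collapse_leaves(self.tree_spec_, k)
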