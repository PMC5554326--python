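"""Structural-conservation statistics across gradient groups.

The conservation metric throughout is the coefficient of variation (CV),
the ratio of the standard deviation to the mean of an index computed in
each gradient group. Because each overall index yields a single CV per
layer, significance is assessed against degree-preserving Maslov–Sneppen
null ensembles: rewired replicates of every group network give a null
distribution of CVs whose spread feeds a Welch t-test between layers.

Node-level conservation compares per-node CV distributions of normalized
connectivity ranks between layers (rank-sum test), cross-validates mean
ranks between the low- and high-gradient halves (distance to the diagonal,
D-values), and examines CVs of pairwise correlation coefficients across
groups, including a column-randomization test of whether the observed mean
pair-CV is smaller than expected if coefficients were shuffled within
groups.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Callable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._seeds import rng_for
from .network import CorrelationMatrix, CorrelationNetwork
from .topology import OVERALL_INDICES, UndefinedMetricError

__all__ = [
    "coefficient_of_variation",
    "maslov_sneppen_rewire",
    "null_cv_ensemble",
    "cv_ttest",
    "shared_nodes",
    "node_cv_comparison",
    "CrossValidation",
    "cross_validate_ranks",
    "pairwise_correlation_cv",
    "compare_cv_distributions_anova",
    "correlation_randomization_test",
]


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample standard deviation (n-1) divided by the mean."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("CV needs at least 2 values")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(arr.std(ddof=1) / mean)


def maslov_sneppen_rewire(
    net: CorrelationNetwork, swap_factor: int = 100, seed: int = 0
) -> CorrelationNetwork:
    """Degree-preserving randomization by repeated double-edge swaps.

    Attempts ``swap_factor * n_edges`` swaps of edge pairs (a-b, c-d) ->
    (a-d, c-b), rejecting any that would create a self-loop or duplicate
    edge, so node count, edge count and the exact degree sequence are
    preserved while edge positions randomize.
    """
    g = net.graph
    m = g.number_of_edges()
    if m < 2:
        warnings.warn("fewer than 2 edges: returning network unchanged", stacklevel=2)
        return net
    rng = rng_for(seed, "ms-rewire")
    edges = [tuple(e) for e in g.edges()]
    edge_set = {frozenset(e) for e in edges}
    n_attempts = swap_factor * m
    idx = rng.integers(0, m, size=(n_attempts, 2))
    flips = rng.random(n_attempts) < 0.5
    for k in range(n_attempts):
        i, j = idx[k]
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if flips[k]:
            c, d = d, c
        # proposed: a-d and c-b
        if a == d or c == b:
            continue
        new1, new2 = frozenset((a, d)), frozenset((c, b))
        if new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard(frozenset((a, b)))
        edge_set.discard(frozenset((c, d)))
        edge_set.add(new1)
        edge_set.add(new2)
        edges[i] = (a, d)
        edges[j] = (c, b)
    rewired = nx.Graph()
    rewired.add_nodes_from(g.nodes)
    rewired.add_edges_from(tuple(e) for e in edge_set)
    return CorrelationNetwork(
        layer=net.layer, group=net.group, graph=rewired, threshold=net.threshold
    )


def null_cv_ensembles(
    networks_by_group: Mapping[str, CorrelationNetwork],
    indices: Sequence[str],
    n_reps: int = 100,
    swap_factor: int = 100,
    seed: int = 0,
) -> dict[str, tuple[float, float, list[float]]]:
    """Null CV distributions of several overall indices at once.

    Replicate k rewires every group's network independently (seed derived
    from (seed, group, k)); each rewired set yields one across-group CV per
    index, so all indices share the same null ensemble of networks. Returns
    per index the (mean, sd, list) of the simulated CVs; replicates on
    which an index is undefined are skipped for that index.
    """
    if len(networks_by_group) < 2:
        raise ValueError("need at least 2 groups")
    if n_reps < 2:
        raise ValueError("need at least 2 replicates")
    fns = {name: OVERALL_INDICES[name] for name in indices}
    null_cvs: dict[str, list[float]] = {name: [] for name in indices}
    skipped = {name: 0 for name in indices}
    for k in range(n_reps):
        rewired = {
            group: maslov_sneppen_rewire(
                net, swap_factor=swap_factor, seed=int(rng_for(seed, group, k).integers(2**31))
            )
            for group, net in networks_by_group.items()
        }
        for name, fn in fns.items():
            try:
                null_cvs[name].append(
                    coefficient_of_variation([fn(net) for net in rewired.values()])
                )
            except (UndefinedMetricError, ValueError):
                skipped[name] += 1
    out: dict[str, tuple[float, float, list[float]]] = {}
    for name in indices:
        if skipped[name]:
            warnings.warn(
                f"{skipped[name]} null replicate(s) skipped for {name}", stacklevel=2
            )
        cvs = null_cvs[name]
        if len(cvs) < 2:
            raise ValueError(f"too few usable null replicates for {name}")
        arr = np.asarray(cvs)
        out[name] = (float(arr.mean()), float(arr.std(ddof=1)), cvs)
    return out


def null_cv_ensemble(
    networks_by_group: Mapping[str, CorrelationNetwork],
    index: str | Callable[[CorrelationNetwork], float],
    n_reps: int = 100,
    swap_factor: int = 100,
    seed: int = 0,
) -> tuple[float, float, list[float]]:
    """Null distribution of the across-group CV of one overall index.

    ``index`` is a name from :data:`menconserve.topology.OVERALL_INDICES`
    or any callable on a network. Seeds match :func:`null_cv_ensembles`, so
    single- and multi-index runs agree replicate for replicate.
    """
    if not callable(index):
        return null_cv_ensembles(
            networks_by_group, [index], n_reps=n_reps, swap_factor=swap_factor, seed=seed
        )[index]
    if len(networks_by_group) < 2:
        raise ValueError("need at least 2 groups")
    if n_reps < 2:
        raise ValueError("need at least 2 replicates")
    null_cvs: list[float] = []
    skipped = 0
    for k in range(n_reps):
        try:
            values = [
                index(
                    maslov_sneppen_rewire(
                        net,
                        swap_factor=swap_factor,
                        seed=int(rng_for(seed, group, k).integers(2**31)),
                    )
                )
                for group, net in networks_by_group.items()
            ]
            null_cvs.append(coefficient_of_variation(values))
        except (UndefinedMetricError, ValueError):
            skipped += 1
    if skipped:
        warnings.warn(f"{skipped} null replicate(s) skipped", stacklevel=2)
    if len(null_cvs) < 2:
        raise ValueError("too few usable null replicates")
    arr = np.asarray(null_cvs)
    return float(arr.mean()), float(arr.std(ddof=1)), null_cvs


def cv_ttest(
    cv_a: float, null_sd_a: float, cv_b: float, null_sd_b: float, n_reps: int = 100
) -> tuple[float, float]:
    """Welch two-sample t-test of two CVs using null-ensemble spreads.

    The standard deviations come from each layer's Maslov–Sneppen ensemble
    (sample size = number of replicates); degrees of freedom by
    Welch–Satterthwaite. Degenerate zero-spread cases: equal CVs give
    (0, 1), unequal give (inf-signed, 0).
    """
    if null_sd_a < 0 or null_sd_b < 0:
        raise ValueError("null standard deviations must be nonnegative")
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    va, vb = null_sd_a**2 / n_reps, null_sd_b**2 / n_reps
    if va + vb == 0:
        if cv_a == cv_b:
            return 0.0, 1.0
        warnings.warn("zero null spread with unequal CVs: degenerate t-test", stacklevel=2)
        return float(np.sign(cv_a - cv_b) * np.inf), 0.0
    t = (cv_a - cv_b) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (n_reps - 1) + vb**2 / (n_reps - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def shared_nodes(presence: Mapping[str, int], min_networks: int = 3) -> set[str]:
    """Nodes present in strictly more than ``min_networks`` networks."""
    return {node for node, count in presence.items() if count > min_networks}


def node_cv_comparison(
    rank_norm_by_layer: Mapping[str, pd.DataFrame],
) -> tuple[pd.Series, dict[tuple[str, str], float]]:
    """CV of each node's normalized rank across groups, compared by layer.

    Each layer supplies a node x group matrix of normalized ranks (NaN
    where the node is absent); nodes with fewer than two present values are
    excluded. Layer pairs are compared by a two-sided Wilcoxon rank-sum
    test on their node-CV distributions.
    """
    cvs: dict[tuple[str, str], float] = {}
    per_layer: dict[str, list[float]] = {}
    for layer, matrix in rank_norm_by_layer.items():
        layer_cvs = []
        for node, row in matrix.iterrows():
            present = row.dropna()
            if len(present) < 2:
                continue
            cv = coefficient_of_variation(present.to_numpy())
            cvs[(layer, node)] = cv
            layer_cvs.append(cv)
        per_layer[layer] = layer_cvs
    wilcoxon_p: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(per_layer, 2):
        if per_layer[a] and per_layer[b]:
            res = stats.ranksums(per_layer[a], per_layer[b])
            wilcoxon_p[(a, b)] = float(res.pvalue)
    index = pd.MultiIndex.from_tuples(cvs.keys(), names=["layer", "node"]) if cvs else None
    return pd.Series(list(cvs.values()), index=index, dtype=float), wilcoxon_p


@dataclasses.dataclass(frozen=True)
class CrossValidation:
    """Low- vs high-gradient mean normalized ranks per node."""

    points: pd.DataFrame  # node -> x (low mean), y (high mean)
    d_values: pd.Series  # node -> distance to the diagonal
    band_fraction: float  # fraction of nodes with |x - y| < band
    slope: float
    intercept: float
    r_value: float
    p_value: float
    excluded: list[str]


def cross_validate_ranks(
    rank_norm: pd.DataFrame,
    low_groups: Sequence[str],
    high_groups: Sequence[str],
    band: float = 20.0,
    d_metric: str = "perpendicular",
) -> CrossValidation:
    """Cross-validate node ranks between the two halves of the gradient.

    x is a node's mean normalized rank over the low-gradient groups, y over
    the high-gradient groups. A node on the diagonal keeps its topological
    position across the gradient; conservation is summarized by D-values
    (distance to the diagonal: |x-y|/sqrt(2) perpendicular, or plain |x-y|),
    the fraction of nodes with |x-y| strictly below ``band`` (on the 1-100
    rank scale), and the least-squares y-on-x regression.
    """
    if d_metric not in ("perpendicular", "vertical"):
        raise ValueError("d_metric must be 'perpendicular' or 'vertical'")
    rows = {}
    excluded = []
    for node, row in rank_norm.iterrows():
        low = row[list(low_groups)].dropna()
        high = row[list(high_groups)].dropna()
        if low.empty or high.empty:
            excluded.append(node)
            continue
        rows[node] = (low.mean(), high.mean())
    if not rows:
        raise ValueError("no node present in both gradient halves")
    points = pd.DataFrame.from_dict(rows, orient="index", columns=["x", "y"])
    diff = (points["x"] - points["y"]).abs()
    d_values = diff / np.sqrt(2.0) if d_metric == "perpendicular" else diff.copy()
    d_values.name = "d_value"
    band_fraction = float((diff < band).mean())
    if points["x"].nunique() > 1:
        reg = stats.linregress(points["x"], points["y"])
        slope, intercept, r_value, p_value = reg.slope, reg.intercept, reg.rvalue, reg.pvalue
    else:
        slope = intercept = r_value = p_value = np.nan
    return CrossValidation(
        points=points,
        d_values=d_values,
        band_fraction=band_fraction,
        slope=float(slope),
        intercept=float(intercept),
        r_value=float(r_value),
        p_value=float(p_value),
        excluded=excluded,
    )


def pairwise_correlation_cv(
    corrs_by_group: Mapping[str, CorrelationMatrix],
    nodes: Sequence[str],
    mean_tol: float = 1e-6,
    use_abs: bool = False,
) -> tuple[pd.Series, int]:
    """CV of each shared pair's correlation coefficient across groups.

    Pairs must have coefficients in at least two groups; pairs whose mean
    coefficient is within ``mean_tol`` of zero have an unstable CV and are
    excluded (their count is returned). ``use_abs`` computes the CV of the
    coefficient magnitudes |r|: for pairs whose correlation changes sign
    along the gradient the signed mean is near zero and the signed CV
    explodes, so magnitude CVs are the comparable dispersion measure when
    layers differ in how often pairs flip sign.
    """
    nodes = sorted(nodes)
    coeffs = pairwise_coefficient_matrix(corrs_by_group, nodes)
    cvs = {}
    excluded = 0
    for pair, row in coeffs.iterrows():
        present = row.dropna()
        if len(present) < 2:
            continue
        arr = present.to_numpy()
        if use_abs:
            arr = np.abs(arr)
        if abs(arr.mean()) <= mean_tol:
            excluded += 1
            continue
        cvs[pair] = float(arr.std(ddof=1) / arr.mean())
    index = pd.MultiIndex.from_tuples(cvs.keys(), names=["node_a", "node_b"]) if cvs else None
    return pd.Series(list(cvs.values()), index=index, dtype=float), excluded


def pairwise_coefficient_matrix(
    corrs_by_group: Mapping[str, CorrelationMatrix], nodes: Sequence[str]
) -> pd.DataFrame:
    """Pair x group matrix of correlation coefficients (NaN where absent)."""
    nodes = sorted(nodes)
    pairs = list(itertools.combinations(nodes, 2))
    data = np.full((len(pairs), len(corrs_by_group)), np.nan)
    groups = list(corrs_by_group)
    for g_idx, group in enumerate(groups):
        corr = corrs_by_group[group]
        pos = {f: i for i, f in enumerate(corr.feature_ids)}
        for p_idx, (a, b) in enumerate(pairs):
            if a in pos and b in pos:
                data[p_idx, g_idx] = corr.r[pos[a], pos[b]]
    return pd.DataFrame(
        data, index=pd.MultiIndex.from_tuples(pairs, names=["node_a", "node_b"]), columns=groups
    )


def compare_cv_distributions_anova(
    cvs_by_layer: Mapping[str, Sequence[float]],
) -> tuple[float, float]:
    """One-way ANOVA of CV distributions across layers: (F, p)."""
    samples = [np.asarray(v, dtype=float) for v in cvs_by_layer.values() if len(v) > 1]
    if len(samples) < 2:
        raise ValueError("ANOVA needs at least two layers with >=2 CVs each")
    res = stats.f_oneway(*samples)
    return float(res.statistic), float(res.pvalue)


def correlation_randomization_test(
    coeffs: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    use_abs: bool = False,
    mean_tol: float = 1e-6,
) -> tuple[float, float]:
    """Column-randomization test of non-random correlation conservation.

    ``coeffs`` is a pair x group matrix of correlation coefficients. The
    observed statistic is the mean row-CV (rows with |mean| <= mean_tol or
    fewer than 2 observed values skipped). Each permutation independently
    shuffles every column and recomputes the statistic; the one-sided
    p-value (1 + #{null <= observed}) / (n_perm + 1) is small when observed
    pair correlations are more conserved across groups than random
    placement would produce. ``use_abs`` computes CVs of absolute
    coefficients. Missing cells (pairs absent from a group) are allowed:
    the missingness mask is held fixed and each column's observed entries
    are permuted among their own positions.
    """
    if coeffs.shape[0] < 2 or coeffs.shape[1] < 2:
        raise ValueError("need at least 2 pairs and 2 groups")
    values = coeffs.to_numpy(dtype=float)
    observed_mask = ~np.isnan(values)
    if (observed_mask.sum(axis=1) >= 2).sum() < 2:
        raise ValueError("need at least 2 pairs with >=2 observed coefficients")
    rng = rng_for(seed, "randomization")

    def mean_row_cv(mat: np.ndarray) -> float:
        m = np.abs(mat) if use_abs else mat
        n_obs = observed_mask.sum(axis=1)
        with np.errstate(invalid="ignore"):
            means = np.nanmean(np.where(observed_mask, m, np.nan), axis=1)
            sds = np.nanstd(np.where(observed_mask, m, np.nan), axis=1, ddof=1)
        ok = (n_obs >= 2) & (np.abs(means) > mean_tol)
        if not ok.any():
            raise ValueError("all rows have near-zero mean: test undefined")
        return float(np.mean(sds[ok] / means[ok]))

    observed = mean_row_cv(values)
    count = 0
    null_mat = values.copy()
    col_positions = [np.flatnonzero(observed_mask[:, c]) for c in range(values.shape[1])]
    for _ in range(n_perm):
        for c, pos in enumerate(col_positions):
            null_mat[pos, c] = values[rng.permutation(pos), c]
        if mean_row_cv(null_mat) <= observed:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return observed, float(p)
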