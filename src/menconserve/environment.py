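"""Relating network characteristics to environmental properties.

Node significance is the squared Spearman correlation between a node's
abundance profile and an environmental variable — a [0, 1] measure of how
tightly the node tracks that variable, insensitive to any monotone
rescaling (so standardizing the environmental data does not change it).
Mantel tests then ask whether nodes that occupy similar topological
positions across the gradient (similar connectivity-score profiles) also
relate similarly to the environment (similar node-significance profiles),
one test per environmental variable.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import braycurtis, pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as _skbio_mantel

from ._seeds import child_seed
from .grouping import Grouping
from .synth import AbundanceTable

__all__ = [
    "MantelResult",
    "node_significance",
    "mantel_test",
    "connectivity_environment_association",
    "bray_curtis_by_group_difference",
]


@dataclasses.dataclass(frozen=True)
class MantelResult:
    variable: str
    r: float
    p: float
    n_perm: int


def node_significance(
    abundances: pd.DataFrame, env_values: pd.Series | Sequence[float]
) -> pd.Series:
    """Squared Spearman correlation of each node's profile with a variable.

    ``abundances`` is node x sample; ``env_values`` aligns with its columns.
    Constant node or environment vectors leave the correlation undefined;
    those nodes get 0 with a warning (matching the absent-node convention).
    """
    env = np.asarray(env_values, dtype=float)
    if abundances.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if env.size != abundances.shape[1]:
        raise ValueError("environment vector does not align with samples")
    out = {}
    n_undefined = 0
    env_constant = np.all(env == env[0])
    for node, row in abundances.iterrows():
        x = row.to_numpy(dtype=float)
        if env_constant or np.all(x == x[0]):
            out[node] = 0.0
            n_undefined += 1
            continue
        rho = stats.spearmanr(x, env).statistic
        out[node] = float(rho**2) if np.isfinite(rho) else 0.0
    if n_undefined:
        warnings.warn(
            f"{n_undefined} node(s) with undefined correlation set to 0", stacklevel=2
        )
    return pd.Series(out, dtype=float)


def mantel_test(
    dist_a: np.ndarray, dist_b: np.ndarray, n_perm: int = 999, seed: int = 0
) -> tuple[float, float]:
    """One-sided Mantel test between two distance matrices.

    r is the Pearson correlation of the upper-triangle entries; the p-value
    comes from simultaneous row/column permutations of one matrix
    (one-sided toward positive association, add-one corrected).
    """
    dist_a = np.asarray(dist_a, dtype=float)
    dist_b = np.asarray(dist_b, dtype=float)
    for d in (dist_a, dist_b):
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrices must be square")
        if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0.0):
            raise ValueError("distance matrices must be symmetric with zero diagonal")
    if dist_a.shape != dist_b.shape:
        raise ValueError("distance matrices must have the same shape")
    tri = np.triu_indices(dist_a.shape[0], k=1)
    if np.std(dist_a[tri]) == 0 or np.std(dist_b[tri]) == 0:
        raise ValueError("Mantel r undefined for constant off-diagonal distances")
    r, p, _ = _skbio_mantel(
        DistanceMatrix(dist_a),
        DistanceMatrix(dist_b),
        method="pearson",
        permutations=n_perm,
        alternative="greater",
        seed=int(child_seed(seed, "mantel").generate_state(1)[0] % 2**31),
    )
    return float(r), float(p)


def connectivity_environment_association(
    scores: pd.DataFrame,
    abundance_by_group: Mapping[str, AbundanceTable],
    env_by_group: Mapping[str, pd.DataFrame],
    n_perm: int = 999,
    seed: int = 0,
) -> list[MantelResult]:
    """Mantel tests linking connectivity-score and node-significance structure.

    ``scores`` is the shared-node x group connectivity-score matrix. For
    each environmental variable, a node x group significance matrix is
    assembled from each group's filtered abundance table (0 where a node is
    absent from the group); Euclidean distances between node row-vectors of
    the two matrices feed :func:`mantel_test`. Variables missing from any
    group's metadata are skipped with a warning.
    """
    if scores.empty:
        raise ValueError("shared-node score matrix is empty")
    groups = list(scores.columns)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    variables = sorted(set.intersection(*(set(env_by_group[g].columns) for g in groups)))
    all_vars = sorted(set.union(*(set(env_by_group[g].columns) for g in groups)))
    skipped = [v for v in all_vars if v not in variables]
    if skipped:
        warnings.warn(f"variables missing from some groups skipped: {skipped}", stacklevel=2)

    dist_scores = squareform(pdist(scores.to_numpy(dtype=float), metric="euclidean"))
    results = []
    for var_idx, var in enumerate(variables):
        sig = pd.DataFrame(0.0, index=scores.index, columns=groups)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for g in groups:
                table = abundance_by_group[g]
                present = [n for n in scores.index if n in table.data.index]
                if not present:
                    continue
                env_vec = env_by_group[g].loc[table.sample_ids, var]
                sig.loc[present, g] = node_significance(
                    table.data.loc[present], env_vec
                ).to_numpy()
        dist_sig = squareform(pdist(sig.to_numpy(dtype=float), metric="euclidean"))
        try:
            r, p = mantel_test(dist_scores, dist_sig, n_perm=n_perm, seed=seed + var_idx)
        except ValueError:
            warnings.warn(f"Mantel undefined for variable {var!r}; skipped", stacklevel=2)
            continue
        results.append(MantelResult(variable=var, r=r, p=p, n_perm=n_perm))
    return results


def bray_curtis_by_group_difference(
    table: AbundanceTable, grouping: Grouping
) -> tuple[dict[int, list[float]], float]:
    """Bray–Curtis similarity of sample pairs, binned by group separation.

    Group Difference is the absolute difference of ordinal group indices
    (G1..Gk -> 0..k-1). Returns similarities (1 - dissimilarity) per bin and
    a one-sided p-value for a decreasing similarity trend with separation
    (Spearman rank correlation over all pairs). Pairs where both samples
    are entirely zero are skipped.
    """
    samples = [s for s in table.sample_ids if s in grouping.assignment]
    if len(samples) < 3:
        raise ValueError("need at least 3 grouped samples")
    values = table.data[samples].to_numpy(dtype=float).T
    indices = [grouping.group_index(grouping.assignment[s]) for s in samples]
    bins: dict[int, list[float]] = {d: [] for d in range(len(grouping.group_labels))}
    deltas, sims = [], []
    for i in range(len(samples)):
        for j in range(i + 1, len(samples)):
            if values[i].sum() == 0 and values[j].sum() == 0:
                continue
            sim = 1.0 - braycurtis(values[i], values[j])
            delta = abs(indices[i] - indices[j])
            bins[delta].append(float(sim))
            deltas.append(delta)
            sims.append(sim)
    if len(set(deltas)) < 2 or len(set(np.round(sims, 12))) < 2:
        return bins, 1.0  # no variation: no evidence of a trend
    res = stats.spearmanr(deltas, sims)
    # one-sided toward decreasing similarity with increasing separation
    trend_p = res.pvalue / 2.0 if res.statistic < 0 else 1.0 - res.pvalue / 2.0
    return bins, float(trend_p)
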