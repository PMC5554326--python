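"""Per-group correlation network construction with RMT threshold selection.

The construction follows the standard molecular-ecological-network recipe:
restrict the abundance table to one gradient group, keep features detected
in more than half of that group's samples, standardize each feature to mean
0 / variance 1, compute all pairwise Pearson correlations, and convert the
similarity matrix to an adjacency matrix at a threshold chosen by the
random-matrix-theory criterion — the smallest cutoff at which the
nearest-neighbor spacing distribution (NNSD) of the thresholded matrix's
unfolded eigenvalues follows the Poisson form (uncorrelated, system-specific
eigenvalues) rather than the Gaussian orthogonal ensemble (GOE) form that
characterizes random noise.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .synth import AbundanceTable

__all__ = [
    "CorrelationMatrix",
    "ThresholdScanResult",
    "CorrelationNetwork",
    "NoThresholdFoundError",
    "prevalence_filter",
    "standardize_features",
    "correlation_matrix",
    "nnsd_chi_square",
    "rmt_threshold",
    "build_network",
]


class NoThresholdFoundError(RuntimeError):
    """No scanned threshold produced a Poisson-like spacing distribution."""


@dataclasses.dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix over a group's retained features."""

    feature_ids: tuple[str, ...]
    r: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        n = len(self.feature_ids)
        if self.r.shape != (n, n):
            raise ValueError("correlation matrix shape does not match feature ids")
        if not np.allclose(self.r, self.r.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if np.nanmax(np.abs(self.r)) > 1 + 1e-8:
            raise ValueError("correlations must lie in [-1, 1]")


@dataclasses.dataclass(frozen=True)
class ThresholdScanResult:
    """Per-candidate NNSD goodness-of-fit and the chosen threshold."""

    candidates: pd.DataFrame  # threshold, chi_sq_poisson, chi_sq_goe, p_poisson, n_spacings
    chosen: float


@dataclasses.dataclass
class CorrelationNetwork:
    """Undirected co-occurrence network with signed correlation weights."""

    layer: str
    group: str
    graph: nx.Graph
    threshold: float

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def prevalence_filter(
    table: AbundanceTable, group_samples: Sequence[str], min_frac: float = 0.5
) -> AbundanceTable:
    """Restrict to a group's samples and its sufficiently-prevalent features.

    A feature is kept when detected (value strictly > 0) in strictly more
    than ``min_frac`` of the group's samples — the ">50% of samples" rule at
    the default.
    """
    group_samples = list(group_samples)
    if not group_samples:
        raise ValueError("group has no samples")
    missing = set(group_samples) - set(table.sample_ids)
    if missing:
        raise ValueError(f"samples not in table: {sorted(missing)}")
    if not 0.0 <= min_frac < 1.0:
        raise ValueError("min_frac must be in [0, 1)")
    sub = table.data[group_samples]
    detected = (sub > 0).sum(axis=1)
    keep = detected > min_frac * len(group_samples)
    return AbundanceTable(
        layer=table.layer,
        data=sub.loc[keep],
        archetypes=None if table.archetypes is None else table.archetypes.loc[keep],
    )


def standardize_features(table: AbundanceTable) -> pd.DataFrame:
    """Z-score each feature row to mean 0, unit sample variance (n-1).

    Zero-variance rows cannot be standardized; they are dropped with a
    warning. Returns a plain DataFrame since standardized values are signed.
    """
    values = table.data.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        dropped = [fid for fid, bad in zip(table.feature_ids, degenerate) if bad]
        warnings.warn(
            f"dropping {len(dropped)} zero-variance feature(s): {dropped[:5]}{'...' if len(dropped) > 5 else ''}",
            stacklevel=2,
        )
    keep = ~degenerate
    z = (values[keep] - values[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    return pd.DataFrame(z, index=table.data.index[keep], columns=table.data.columns)


def correlation_matrix(standardized: pd.DataFrame) -> CorrelationMatrix:
    """Pairwise Pearson correlations between feature rows."""
    n_features, n_samples = standardized.shape
    if n_samples < 3:
        raise ValueError("need at least 3 samples for correlations")
    if n_features < 2:
        raise ValueError("need at least 2 features for correlations")
    r = np.corrcoef(standardized.to_numpy(dtype=float))
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(
        feature_ids=tuple(standardized.index), r=r, n_samples=n_samples
    )


def _unfold_eigenvalues(eigs: np.ndarray) -> np.ndarray:
    """Map eigenvalues through a smooth monotone estimate of the spectral CDF.

    The estimate is the Gaussian-kernel-smoothed integrated density
    N(x) = sum_j Phi((x - eig_j)/h), which is monotone by construction;
    evaluating it at the (deduplicated, sorted) eigenvalues yields unfolded
    values whose successive spacings have unit mean after normalization.
    """
    eigs = np.sort(eigs)
    # collapse numerically-degenerate eigenvalues: their spacings are artifacts
    keep = np.concatenate([[True], np.diff(eigs) > 1e-8])
    eigs = eigs[keep]
    n = eigs.size
    if n < 3:
        return np.array([])
    # robust bandwidth: the IQR guard keeps a few extreme eigenvalues (the
    # large block/module eigenvalues of similarity matrices) from inflating
    # the smoothing scale far beyond the bulk spacing scale
    sd = eigs.std(ddof=1)
    iqr = float(np.subtract(*np.percentile(eigs, [75, 25])))
    scale = min(sd, iqr / 1.34) if iqr > 0 else sd
    h = 1.06 * scale * n ** (-1 / 5) if scale > 0 else 1.0
    unfolded = stats.norm.cdf((eigs[None, :] - eigs[:, None]) / h).sum(axis=0)
    return np.sort(unfolded)


def _spacings(matrix: np.ndarray) -> np.ndarray:
    """Unit-mean nearest-neighbor spacings of a symmetric matrix's spectrum."""
    eigs = np.linalg.eigvalsh(matrix)
    unfolded = _unfold_eigenvalues(eigs)
    if unfolded.size < 2:
        return np.array([])
    s = np.diff(unfolded)
    s = s[s > 0]
    if s.size == 0:
        return s
    return s / s.mean()


def nnsd_chi_square(
    matrix: np.ndarray, s_max: float = 3.0, n_bins: int | None = None
) -> tuple[float, float, float, int]:
    """Chi-square distances of the NNSD to the Poisson and GOE forms.

    Spacings are binned in equal-width bins over [0, s_max]; expected counts
    integrate the Poisson density exp(-s) and the GOE (Wigner surmise)
    density (pi*s/2)*exp(-pi*s^2/4) over each bin. Returns
    (chi_sq_poisson, chi_sq_goe, p_poisson, n_spacings); the p-value is for
    the Poisson fit with n_bins - 1 degrees of freedom.
    """
    s = _spacings(matrix)
    n = s.size
    if n < 2:
        return np.inf, np.inf, 0.0, n
    if n_bins is None:
        n_bins = int(np.clip(n // 8, 5, 25))
    edges = np.linspace(0.0, s_max, n_bins + 1)
    observed, _ = np.histogram(s, bins=edges)
    poisson_cdf = 1.0 - np.exp(-edges)
    goe_cdf = 1.0 - np.exp(-np.pi * edges**2 / 4.0)
    exp_poisson = n * np.diff(poisson_cdf)
    exp_goe = n * np.diff(goe_cdf)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi_p = float(np.sum((observed - exp_poisson) ** 2 / exp_poisson))
        chi_g = float(np.sum((observed - exp_goe) ** 2 / exp_goe))
    p_poisson = float(stats.chi2.sf(chi_p, df=n_bins - 1))
    return chi_p, chi_g, p_poisson, n


def rmt_threshold(
    corr: CorrelationMatrix,
    t_min: float = 0.30,
    t_max: float = 0.99,
    step: float = 0.01,
    alpha: float = 0.05,
    min_spacings: int = 20,
    consecutive: int = 1,
    on_fail: str = "raise",
) -> ThresholdScanResult:
    """Scan correlation cutoffs for the RMT Poisson-transition threshold.

    For each candidate t the matrix is thresholded (entries with |r| < t
    zeroed, unit diagonal kept) and the NNSD of its unfolded eigenvalues is
    tested against the Poisson and GOE forms. The chosen threshold is the
    smallest t whose Poisson fit is accepted (chi-square p > ``alpha``) and
    fits better than GOE; to keep the choice stable on small matrices,
    acceptance must hold for ``consecutive`` successive candidates (set 1
    to accept on a single candidate). Candidates with fewer than
    ``min_spacings`` distinct spacings are skipped.

    If no candidate is formally accepted, ``on_fail='raise'`` raises
    :class:`NoThresholdFoundError` (the caller may widen the range) while
    ``on_fail='best'`` falls back to the usable candidate with the best
    Poisson fit that still beats GOE, with a warning.
    """
    if on_fail not in ("raise", "best"):
        raise ValueError("on_fail must be 'raise' or 'best'")
    if not t_min < t_max:
        raise ValueError("t_min must be < t_max")
    if consecutive < 1:
        raise ValueError("consecutive must be >= 1")
    rows = []
    accepted = []
    for t in np.arange(t_min, t_max + step / 2, step):
        m = np.where(np.abs(corr.r) >= t, corr.r, 0.0)
        np.fill_diagonal(m, 1.0)
        chi_p, chi_g, p_poisson, n_sp = nnsd_chi_square(m)
        usable = n_sp >= min_spacings
        accepted.append(usable and p_poisson > alpha and chi_p < chi_g)
        rows.append(
            {
                "threshold": round(float(t), 10),
                "chi_sq_poisson": chi_p,
                "chi_sq_goe": chi_g,
                "p_poisson": p_poisson,
                "n_spacings": n_sp,
                "usable": usable,
            }
        )
    chosen = None
    for i in range(len(accepted) - consecutive + 1):
        if all(accepted[i : i + consecutive]):
            chosen = rows[i]["threshold"]
            break
    candidates = pd.DataFrame(rows)
    if chosen is None and on_fail == "best":
        ok = candidates[candidates["usable"] & (candidates["chi_sq_poisson"] < candidates["chi_sq_goe"])]
        if ok.empty:
            ok = candidates[candidates["usable"]]
        if not ok.empty:
            chosen = float(ok.loc[ok["p_poisson"].idxmax(), "threshold"])
        else:
            # matrix too small for spacing statistics anywhere in the scan:
            # take the most spacing-rich candidate so the caller still gets
            # a defined (if weakly supported) network
            by_info = candidates.sort_values(
                ["n_spacings", "p_poisson"], ascending=False
            )
            chosen = float(by_info.iloc[0]["threshold"])
        warnings.warn(
            f"no threshold formally accepted; falling back to best available fit t={chosen}",
            stacklevel=2,
        )
    if chosen is None:
        raise NoThresholdFoundError(
            "no candidate threshold gave a Poisson-like spacing distribution; "
            "consider widening the scan range"
        )
    return ThresholdScanResult(candidates=candidates, chosen=round(chosen, 10))


def build_network(
    corr: CorrelationMatrix, threshold: float, layer: str = "", group: str = ""
) -> CorrelationNetwork:
    """Adjacency at |r| >= threshold, keeping signed weights, no isolates."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    g = nx.Graph()
    ids = corr.feature_ids
    i_idx, j_idx = np.where(np.triu(np.abs(corr.r) >= threshold, k=1))
    for i, j in zip(i_idx, j_idx):
        g.add_edge(ids[i], ids[j], weight=float(corr.r[i, j]))
    if g.number_of_edges() == 0:
        warnings.warn(f"network {layer}/{group}: no edges at threshold {threshold}", stacklevel=2)
    return CorrelationNetwork(layer=layer, group=group, graph=g, threshold=threshold)
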