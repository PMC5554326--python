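"""Synthetic gradient-structured community data.

Generates the inputs the network-conservation analysis assumes: a set of
samples ordered along an environmental pH gradient with correlated
environmental covariates, and one or more feature-by-sample abundance
tables ("layers": a species-like layer of OTU relative abundances and
trait-like layers of functional-gene signal intensities or gene-family
abundances).

Each feature follows one of five response archetypes along the gradient:

* ``linear_up`` / ``linear_down`` — abundance an increasing/decreasing
  affine function of pH, clipped at zero;
* ``unimodal`` — a Gaussian bump with an optimum pH;
* ``log_unimodal`` — a Gaussian bump in log(pH);
* ``stochastic`` — a stationary random fluctuation along the gradient: a
  smooth random curve in log-abundance with no systematic pH trend, so a
  stochastic feature co-varies strongly with its neighbors *within* a
  narrow gradient window but its correlation partners change from window
  to window.

Layers differ in their archetype mixture: trait-like layers are
deterministic-heavy (most features respond predictably to pH) while the
species-like layer is stochastic-heavy. Observed abundances are the
archetype expectation times multiplicative lognormal noise, with optional
random dropout so downstream prevalence filtering has work to do.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from ._seeds import rng_for

__all__ = [
    "SampleMetadata",
    "ArchetypeSpec",
    "AbundanceTable",
    "ARCHETYPE_KINDS",
    "SPECIES_PRESET",
    "TRAIT_PRESET",
    "DEFAULT_ENV_CORRS",
    "generate_metadata",
    "archetype_response",
    "generate_layer",
    "planted_two_block_correlation",
]

ARCHETYPE_KINDS = ("linear_up", "linear_down", "unimodal", "log_unimodal", "stochastic")

#: Archetype mixture of the species-like layer: mostly stochastic responders.
SPECIES_PRESET: dict[str, float] = {
    "linear_up": 0.075,
    "linear_down": 0.075,
    "unimodal": 0.15,
    "stochastic": 0.70,
}

#: Archetype mixture of trait-like layers: mostly deterministic responders.
TRAIT_PRESET: dict[str, float] = {
    "linear_up": 0.20,
    "linear_down": 0.20,
    "unimodal": 0.30,
    "log_unimodal": 0.10,
    "stochastic": 0.20,
}

#: Fourteen environmental covariates of an acid-mine-drainage survey and a
#: plausible sign/strength of their correlation with solution pH
#: (conductivity and dissolved metals fall as pH rises, etc.).
DEFAULT_ENV_CORRS: dict[str, float] = {
    "EC": -0.8,
    "DO": 0.5,
    "TOC": 0.4,
    "P": 0.3,
    "SO4": -0.7,
    "Fe3": -0.8,
    "Fe2": -0.6,
    "Al": -0.7,
    "As": -0.5,
    "Cd": -0.6,
    "Cu": -0.6,
    "Pb": -0.4,
    "Zn": -0.6,
    "Mg": -0.3,
}


@dataclasses.dataclass(frozen=True)
class SampleMetadata:
    """Per-sample gradient position and environmental covariates.

    ``env`` is a samples x variables DataFrame aligned with ``sample_ids``;
    it may have zero columns.
    """

    sample_ids: tuple[str, ...]
    ph: pd.Series  # indexed by sample id
    env: pd.DataFrame  # samples x variables

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids must be unique")
        if not np.all(np.isfinite(self.ph.to_numpy(dtype=float))):
            raise ValueError("pH values must be finite")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclasses.dataclass(frozen=True)
class ArchetypeSpec:
    """One feature's response curve along the gradient."""

    kind: str
    params: Mapping[str, float] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ARCHETYPE_KINDS:
            raise ValueError(f"unknown archetype kind: {self.kind!r}")


@dataclasses.dataclass
class AbundanceTable:
    """Nonnegative feature-by-sample abundance matrix for one data layer.

    ``archetypes`` records the generating archetype of each feature when the
    table is synthetic (None for loaded data); it exists so tests can check
    recovered structure against the planted one.
    """

    layer: str
    data: pd.DataFrame  # features x samples
    archetypes: pd.Series | None = None  # feature id -> archetype kind

    def __post_init__(self) -> None:
        values = self.data.to_numpy(dtype=float)
        if values.size and values.min() < 0:
            raise ValueError("abundance values must be nonnegative")
        if self.data.index.has_duplicates:
            raise ValueError("feature ids must be unique")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


def generate_metadata(
    n_samples: int = 40,
    ph_min: float = 1.86,
    ph_max: float = 4.10,
    env_corrs: Mapping[str, float] | None = None,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> SampleMetadata:
    """Simulate samples spanning a pH gradient with correlated covariates.

    pH values are drawn uniformly over [ph_min, ph_max], the endpoints are
    pinned so the gradient is fully spanned, and samples are sorted by pH.
    Each environmental variable is an affine function of (standardized) pH
    whose slope is chosen so its population Pearson correlation with pH
    equals the requested value once Gaussian noise of scale ``noise_sd`` is
    added; at |corr| = 1 the noise is suppressed (the target is attainable
    only noise-free).
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if not ph_min < ph_max:
        raise ValueError("ph_min must be < ph_max")
    if env_corrs is None:
        env_corrs = DEFAULT_ENV_CORRS
    for var, rho in env_corrs.items():
        if not -1.0 <= rho <= 1.0:
            raise ValueError(f"env correlation for {var!r} outside [-1, 1]")

    rng = rng_for(seed, "metadata")
    ph = np.sort(rng.uniform(ph_min, ph_max, size=n_samples))
    ph[0], ph[-1] = ph_min, ph_max

    sample_ids = tuple(f"S{i + 1:02d}" for i in range(n_samples))
    ph_series = pd.Series(ph, index=list(sample_ids), name="ph")

    z = (ph - ph.mean()) / ph.std(ddof=0) if ph.std(ddof=0) > 0 else np.zeros_like(ph)
    env_cols: dict[str, np.ndarray] = {}
    for var, rho in env_corrs.items():
        noise = rng.normal(0.0, 1.0, size=n_samples)
        if abs(rho) == 1.0 or noise_sd == 0.0:
            env_cols[var] = rho * z
        else:
            # slope a with corr(a*z + noise_sd*eps, z) == rho
            a = np.sign(rho) * noise_sd * abs(rho) / np.sqrt(1.0 - rho**2)
            env_cols[var] = a * z + noise_sd * noise
    env = pd.DataFrame(env_cols, index=list(sample_ids))
    return SampleMetadata(sample_ids=sample_ids, ph=ph_series, env=env)


def archetype_response(
    spec: ArchetypeSpec, ph: float | np.ndarray, rng: np.random.Generator | None = None
) -> float | np.ndarray:
    """Expected abundance of a feature at the given pH.

    Deterministic kinds evaluate their closed-form curve (clipped at zero);
    the ``stochastic`` kind draws a smooth stationary random curve over the
    gradient (no systematic pH trend) and requires ``rng``.
    """
    p = spec.params
    ph = np.asarray(ph, dtype=float)
    scalar = ph.ndim == 0
    if scalar:
        ph = ph.reshape(1)
    if spec.kind == "linear_up":
        out = p.get("intercept", 0.0) + abs(p.get("slope", 1.0)) * ph
    elif spec.kind == "linear_down":
        out = p.get("intercept", 10.0) - abs(p.get("slope", 1.0)) * ph
    elif spec.kind == "unimodal":
        opt = p.get("optimum", 3.0)
        width = p.get("width", 0.5)
        out = p.get("baseline", 0.0) + p.get("height", 1.0) * np.exp(
            -((ph - opt) ** 2) / (2.0 * width**2)
        )
    elif spec.kind == "log_unimodal":
        opt = p.get("optimum", 3.0)
        width = p.get("width", 0.2)
        out = p.get("baseline", 0.0) + p.get("height", 1.0) * np.exp(
            -((np.log(ph) - np.log(opt)) ** 2) / (2.0 * width**2)
        )
    elif spec.kind == "stochastic":
        if rng is None:
            raise ValueError("stochastic archetype needs a random generator")
        # stationary random fluctuation: a smooth random curve in
        # log-abundance over the gradient (cubic interpolation through
        # Gaussian knot values), with no systematic pH trend
        lo = p.get("domain_lo", float(ph.min()) if ph.size else 0.0)
        hi = p.get("domain_hi", float(ph.max()) if ph.size else 1.0)
        pad = 0.1 * (hi - lo) + 1e-9
        knots = np.linspace(lo - pad, hi + pad, int(p.get("n_knots", 8)))
        amp = p.get("amplitude", 0.8)
        values = rng.normal(0.0, amp, size=knots.size)
        curve = CubicSpline(knots, values)(ph)
        if ph.size >= 3 and ph.std() > 0:
            # damp (not remove) the incidental linear pH component: the
            # fluctuation should carry no systematic gradient trend on
            # average, yet keep a residual low-frequency part — a fully
            # detrended curve would be orthogonal to every monotone
            # responder by construction, which real sporadic taxa are not
            slope, intercept = np.polyfit(ph, curve, 1)
            curve = curve - 0.75 * (slope * ph + intercept)
        out = p.get("scale", 1.0) * np.exp(curve)
    else:  # pragma: no cover - guarded by ArchetypeSpec
        raise ValueError(f"unknown archetype kind: {spec.kind!r}")
    out = np.maximum(out, 0.0)
    return float(out[0]) if scalar else out


def _draw_archetype_spec(kind: str, ph_lo: float, ph_hi: float, rng: np.random.Generator) -> ArchetypeSpec:
    """Randomized per-feature curve parameters, nonnegative over the domain.

    Deterministic curves are parameterized so their *relative* variation
    within a narrow slice of the gradient is substantial: linear responses
    are anchored just outside the gradient (abundance proportional to the
    distance from an edge-adjacent zero point) and bumps are narrow relative
    to the gradient span. This is what lets deterministically responding
    features correlate strongly within each gradient group, the premise of
    the trait-conservation contrast.
    """
    span = ph_hi - ph_lo
    if kind == "linear_up":
        slope = rng.uniform(0.5, 2.0)
        zero_at = ph_lo - rng.uniform(0.3, 1.2) * span
        return ArchetypeSpec(kind, {"slope": slope, "intercept": -slope * zero_at})
    if kind == "linear_down":
        slope = rng.uniform(0.5, 2.0)
        zero_at = ph_hi + rng.uniform(0.3, 1.2) * span
        return ArchetypeSpec(kind, {"slope": slope, "intercept": slope * zero_at})
    if kind in ("unimodal", "log_unimodal"):
        return ArchetypeSpec(
            kind,
            {
                "optimum": rng.uniform(ph_lo, ph_hi),
                "width": rng.uniform(0.4, 0.8) * span
                if kind == "unimodal"
                else rng.uniform(0.3, 0.6),
                "height": rng.uniform(1.0, 4.0),
                "baseline": 0.0,
            },
        )
    return ArchetypeSpec(
        kind,
        {
            "scale": rng.uniform(0.5, 2.0),
            "amplitude": rng.uniform(0.5, 1.2),
            "n_knots": 8,
            "domain_lo": ph_lo,
            "domain_hi": ph_hi,
        },
    )


def generate_layer(
    metadata: SampleMetadata,
    n_features: int = 150,
    archetype_weights: Mapping[str, float] | None = None,
    noise_cv: float = 0.05,
    noise_heterogeneity: float = 1.0,
    dropout: float = 0.05,
    detection_quantile: float = 0.3,
    latent_amplitude: float = 0.0,
    layer: str = "layer",
    seed: int = 0,
) -> AbundanceTable:
    """Simulate one abundance layer over the metadata's samples.

    Each feature is assigned an archetype with probability proportional to
    ``archetype_weights`` and parameterized at random; its expected value at
    each sample's pH comes from :func:`archetype_response`. Observed values
    multiply the expectation by lognormal noise with coefficient of
    variation ``noise_cv`` (mean-one, so expectations are preserved) —
    each feature's own noise level is ``noise_cv`` scaled by a lognormal
    factor with log-sd ``noise_heterogeneity``, so features differ
    reproducibly in how tightly the gradient governs them — then
    cells are zeroed by two detection mechanisms. A detection limit zeroes
    each feature's lowest ``detection_quantile`` fraction of values, so a
    feature is systematically undetected in the part of the gradient where
    it is rare (zeros are spatially coherent along the gradient, which is
    what lets contiguous pH groups pass the prevalence filter cleanly while
    randomly composed groups fail it erratically). On top of that, each
    feature gets a random dropout rate (lognormal around ``dropout``,
    capped at 0.9) zeroing cells independently — sporadic non-detection.
    Species-like tables are much sparser than trait-like ones (most taxa
    occupy a narrow part of the gradient).

    Besides pH, communities respond to co-varying secondary drivers (metal
    concentrations, redox state) that change along the gradient but are not
    functions of pH. This is modeled as one smooth latent factor curve over
    the gradient (log-scale amplitude ``latent_amplitude``) on which each
    feature loads with its own random sensitivity in [-1, 1]. Within a
    narrow pH group the factor is nearly constant and barely perturbs
    correlations; across a randomly composed group it varies fully and
    decorrelates features with unlike loadings.
    """
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    weights = dict(archetype_weights or TRAIT_PRESET)
    if any(w < 0 for w in weights.values()):
        raise ValueError("archetype weights must be nonnegative")
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("archetype weights must sum to a positive value")
    for kind in weights:
        if kind not in ARCHETYPE_KINDS:
            raise ValueError(f"unknown archetype kind: {kind!r}")
    if not 0.0 <= dropout < 1.0:
        raise ValueError("dropout must be in [0, 1)")

    rng = rng_for(seed, "layer", layer)
    kinds = list(weights)
    probs = np.array([weights[k] for k in kinds], dtype=float) / total
    ph = metadata.ph.to_numpy(dtype=float)
    ph_lo, ph_hi = float(ph.min()), float(ph.max())

    assigned = rng.choice(len(kinds), size=n_features, p=probs)
    values = np.empty((n_features, metadata.n_samples))
    archetypes = []
    if latent_amplitude > 0:
        pad = 0.1 * (ph_hi - ph_lo) + 1e-9
        knots = np.linspace(ph_lo - pad, ph_hi + pad, 5)
        latent = CubicSpline(knots, rng.normal(0.0, latent_amplitude, size=knots.size))(ph)
    systematic = np.empty_like(values)
    for i in range(n_features):
        kind = kinds[assigned[i]]
        archetypes.append(kind)
        spec = _draw_archetype_spec(kind, ph_lo, ph_hi, rng)
        expected = np.asarray(archetype_response(spec, ph, rng=rng), dtype=float)
        if latent_amplitude > 0:
            expected = expected * np.exp(rng.uniform(-1.0, 1.0) * latent)
        systematic[i] = expected
        if noise_cv > 0:
            # heterogeneous residual noise: features differ in how tightly
            # the gradient governs them, which gives deterministic features
            # a reproducible hierarchy of correlation strength (and hence of
            # network connectivity) instead of an exchangeable block
            cv_i = noise_cv * float(np.exp(rng.normal(0.0, noise_heterogeneity)))
            sigma = np.sqrt(np.log1p(cv_i**2))
            noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=expected.shape)
            expected = expected * noise
        values[i] = expected
    if not 0.0 <= detection_quantile < 1.0:
        raise ValueError("detection_quantile must be in [0, 1)")
    if detection_quantile > 0:
        # detection keyed on the systematic abundance component, so a
        # feature is undetected in the contiguous part of the gradient
        # where it is rare rather than in random cells
        limits = np.quantile(systematic, detection_quantile, axis=1, keepdims=True)
        values[systematic < limits] = 0.0
    if dropout > 0:
        rates = np.minimum(0.9, dropout * np.exp(rng.normal(0.0, 0.6, size=n_features)))
        values[rng.random(values.shape) < rates[:, None]] = 0.0

    feature_ids = [f"{layer}_f{i + 1:04d}" for i in range(n_features)]
    data = pd.DataFrame(values, index=feature_ids, columns=list(metadata.sample_ids))
    return AbundanceTable(
        layer=layer,
        data=data,
        archetypes=pd.Series(archetypes, index=feature_ids, name="archetype"),
    )


def planted_two_block_correlation(
    n_per_block: int = 40,
    loading_low: float = 0.78,
    loading_high: float = 0.995,
    between_max: float = 0.25,
    seed: int = 0,
) -> tuple[np.ndarray, list[str], set[tuple[str, str]]]:
    """A two-block similarity matrix with known edge structure.

    Each block is a single-factor correlation structure: feature i carries a
    loading a_i drawn uniformly in [loading_low, loading_high] and
    within-block entries are r_ij = a_i * a_j (all strongly positive), the
    correlation pattern of features driven by one shared latent factor plus
    independent noise. Between-block entries are uniform in
    [-between_max, between_max]. Returns the symmetric unit-diagonal matrix,
    feature ids, and the set of true (within-block) edges — the ground truth
    for threshold-recovery checks.
    """
    rng = rng_for(seed, "planted")
    n = 2 * n_per_block
    r = rng.uniform(-between_max, between_max, size=(n, n))
    for b in range(2):
        lo, hi = b * n_per_block, (b + 1) * n_per_block
        a = rng.uniform(loading_low, loading_high, size=n_per_block)
        r[lo:hi, lo:hi] = np.outer(a, a)
    r = np.triu(r, k=1)
    r = r + r.T
    np.fill_diagonal(r, 1.0)
    ids = [f"f{i:03d}" for i in range(n)]
    truth = {
        (ids[i], ids[j])
        for b in range(2)
        for i in range(b * n_per_block, (b + 1) * n_per_block)
        for j in range(i + 1, (b + 1) * n_per_block)
    }
    return r, ids, truth
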