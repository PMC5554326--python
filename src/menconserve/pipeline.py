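"""End-to-end orchestration of the network-conservation analysis.

``run_pipeline`` executes the full chain — simulate or load tables, group
samples along the gradient, filter/standardize/correlate per group, select
RMT thresholds, build one network per (layer, group), compute topology,
conservation statistics, and environment associations — from a single
:class:`RunConfig`, with every stochastic stage seeded from one master
seed. The result is an in-memory :class:`ReportBundle`; ``write_bundle``
serializes it to a directory of TSV/JSON/GraphML files with a manifest.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as mio
from ._seeds import rng_for
from .conservation import (
    coefficient_of_variation,
    compare_cv_distributions_anova,
    correlation_randomization_test,
    cross_validate_ranks,
    cv_ttest,
    node_cv_comparison,
    null_cv_ensembles,
    pairwise_coefficient_matrix,
    pairwise_correlation_cv,
    shared_nodes,
    CrossValidation,
)
from .environment import (
    MantelResult,
    bray_curtis_by_group_difference,
    connectivity_environment_association,
)
from .grouping import Grouping, assign_ph_groups, random_grouping
from .network import (
    CorrelationMatrix,
    CorrelationNetwork,
    NoThresholdFoundError,
    ThresholdScanResult,
    build_network,
    correlation_matrix,
    prevalence_filter,
    rmt_threshold,
    standardize_features,
)
from .synth import (
    AbundanceTable,
    SampleMetadata,
    SPECIES_PRESET,
    TRAIT_PRESET,
    generate_layer,
    generate_metadata,
)
from .topology import (
    TopologySummary,
    connectivity_scores,
    node_profiles,
    summarize_topology,
)

logger = logging.getLogger("menconserve")

__all__ = ["LayerSpec", "RunConfig", "ReportBundle", "run_pipeline", "write_bundle"]

_PRESETS = {"species": SPECIES_PRESET, "trait": TRAIT_PRESET}


@dataclasses.dataclass(frozen=True)
class LayerSpec:
    """Simulation recipe for one abundance layer."""

    name: str
    preset: str = "trait"  # 'species' | 'trait'
    n_features: int = 200
    noise_cv: float = 0.05
    noise_heterogeneity: float = 1.0
    dropout: float = 0.05
    detection_quantile: float = 0.30
    weights: Mapping[str, float] | None = None  # overrides preset

    def archetype_weights(self) -> Mapping[str, float]:
        if self.weights is not None:
            return self.weights
        return _PRESETS[self.preset]


@dataclasses.dataclass
class RunConfig:
    """Everything a run needs; defaults mirror the study design constants."""

    # either a simulation spec ...
    layers: Sequence[LayerSpec] = (
        LayerSpec(name="species", preset="species", noise_cv=0.3, dropout=0.45, detection_quantile=0.0),
        LayerSpec(name="trait1", preset="trait"),
        LayerSpec(name="trait2", preset="trait"),
    )
    n_samples: int = 40
    ph_min: float = 1.86
    ph_max: float = 4.10
    # ... or paths to existing tables
    table_paths: Mapping[str, str] | None = None  # layer name -> abundance TSV
    metadata_path: str | None = None

    n_groups: int = 6
    grouping_mode: str = "gradient"  # 'gradient' | 'random'
    min_prevalence: float = 0.5
    t_min: float = 0.30
    t_max: float = 0.99
    t_step: float = 0.01
    min_shared_networks: int = 3
    n_null: int = 100
    swap_factor: int = 100
    n_perm: int = 999
    band: float = 20.0
    d_metric: str = "perpendicular"
    env_n_perm: int = 999
    # CV of pair correlations on magnitudes |r| (sign-flipping pairs have
    # near-zero signed means, making signed CVs unusable for comparison)
    cv_use_abs: bool = True
    seed: int = 0

    def validate(self) -> None:
        if (self.table_paths is None) != (self.metadata_path is None):
            raise ValueError("table_paths and metadata_path must be given together")
        if self.grouping_mode not in ("gradient", "random"):
            raise ValueError("grouping_mode must be 'gradient' or 'random'")
        if self.n_groups < 2:
            raise ValueError("n_groups must be >= 2")


@dataclasses.dataclass
class ReportBundle:
    """Everything the pipeline computes, keyed by layer and group."""

    config: RunConfig
    metadata: SampleMetadata
    tables: dict[str, AbundanceTable]
    grouping: Grouping
    filtered: dict[tuple[str, str], AbundanceTable]  # (layer, group)
    correlations: dict[tuple[str, str], CorrelationMatrix]
    threshold_scans: dict[tuple[str, str], ThresholdScanResult]
    networks: dict[tuple[str, str], CorrelationNetwork]
    topology: pd.DataFrame  # one row per network
    profiles: pd.DataFrame  # long node profiles
    overall_cvs: pd.DataFrame  # layer x index observed CVs
    null_stats: pd.DataFrame  # layer x index null mean/sd
    cv_ttests: pd.DataFrame  # layer pair x index t/p
    shared: dict[str, set[str]]
    rank_norm_matrices: dict[str, pd.DataFrame]
    node_cvs: pd.Series
    node_cv_wilcoxon: dict[tuple[str, str], float]
    cross_validation: dict[str, CrossValidation]
    d_value_anova: tuple[float, float] | None
    pair_cvs: dict[str, pd.Series]
    pair_cv_excluded: dict[str, int]
    pair_cv_anova: tuple[float, float] | None
    randomization: dict[str, tuple[float, float]]  # layer -> (observed mean CV, p)
    mantel: dict[str, list[MantelResult]]
    bray_curtis: dict[str, tuple[dict[int, list[float]], float]]
    soft_errors: list[str]


def _load_or_simulate(config: RunConfig) -> tuple[SampleMetadata, dict[str, AbundanceTable]]:
    if config.table_paths is not None:
        metadata = mio.read_metadata_tsv(config.metadata_path)
        tables = {
            name: mio.read_abundance_tsv(path, layer=name)
            for name, path in config.table_paths.items()
        }
        return metadata, tables
    metadata = generate_metadata(
        n_samples=config.n_samples,
        ph_min=config.ph_min,
        ph_max=config.ph_max,
        seed=config.seed,
    )
    tables = {
        spec.name: generate_layer(
            metadata,
            n_features=spec.n_features,
            archetype_weights=spec.archetype_weights(),
            noise_cv=spec.noise_cv,
            noise_heterogeneity=spec.noise_heterogeneity,
            dropout=spec.dropout,
            detection_quantile=spec.detection_quantile,
            layer=spec.name,
            seed=config.seed,
        )
        for spec in config.layers
    }
    return metadata, tables


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full analysis described by ``config``."""
    config.validate()
    soft_errors: list[str] = []
    metadata, tables = _load_or_simulate(config)
    logger.info("inputs: %d samples, layers %s", metadata.n_samples, list(tables))

    if config.grouping_mode == "gradient":
        grouping = assign_ph_groups(metadata, n_groups=config.n_groups)
    else:
        sizes = list(assign_ph_groups(metadata, n_groups=config.n_groups).sizes.values())
        grouping = random_grouping(metadata, sizes, seed=config.seed)
    groups = list(grouping.group_labels)

    # --- per (layer, group): filter -> standardize -> correlate -> threshold -> network
    filtered: dict[tuple[str, str], AbundanceTable] = {}
    correlations: dict[tuple[str, str], CorrelationMatrix] = {}
    scans: dict[tuple[str, str], ThresholdScanResult] = {}
    networks: dict[tuple[str, str], CorrelationNetwork] = {}
    for layer, table in tables.items():
        for group in groups:
            key = (layer, group)
            sub = prevalence_filter(
                table, grouping.samples_in(group), min_frac=config.min_prevalence
            )
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                z = standardize_features(sub)
                for w in caught:
                    soft_errors.append(f"{layer}/{group}: {w.message}")
            filtered[key] = AbundanceTable(layer=layer, data=sub.data.loc[z.index])
            corr = correlation_matrix(z)
            correlations[key] = corr
            try:
                with warnings.catch_warnings(record=True) as caught:
                    warnings.simplefilter("always")
                    scan = rmt_threshold(
                        corr, t_min=config.t_min, t_max=config.t_max,
                        step=config.t_step, on_fail="best",
                    )
                for w in caught:
                    soft_errors.append(f"threshold {layer}/{group}: {w.message}")
            except NoThresholdFoundError as exc:
                raise NoThresholdFoundError(f"{layer}/{group}: {exc}") from exc
            scans[key] = scan
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                networks[key] = build_network(corr, scan.chosen, layer=layer, group=group)
            logger.info(
                "network %s/%s: %d features -> threshold %.2f, %d nodes, %d edges",
                layer, group, corr.r.shape[0], scan.chosen,
                networks[key].n_nodes, networks[key].n_edges,
            )

    # --- topology
    topo_rows = []
    for (layer, group), net in networks.items():
        try:
            s = summarize_topology(net)
            topo_rows.append(dataclasses.asdict(s))
        except Exception as exc:  # edgeless network: indices undefined
            soft_errors.append(f"topology {layer}/{group}: {exc}")
    topology = pd.DataFrame(topo_rows)
    profiles = node_profiles(list(networks.values()))

    # --- overall CVs, null ensembles, t-tests
    indices = ["avg_gd", "avg_cc", "modularity"]
    layers = list(tables)
    overall_rows, null_rows = [], []
    nulls: dict[tuple[str, str], tuple[float, float, list[float]]] = {}
    for layer in layers:
        nets = {g: networks[(layer, g)] for g in groups if (layer, g) in networks}
        sub = topology[topology["layer"] == layer]
        ensembles = null_cv_ensembles(
            nets, indices, n_reps=config.n_null,
            swap_factor=config.swap_factor, seed=config.seed,
        )
        for index in indices:
            observed = coefficient_of_variation(sub[index].to_numpy())
            mean, sd, cvs = ensembles[index]
            nulls[(layer, index)] = (mean, sd, cvs)
            overall_rows.append({"layer": layer, "index": index, "cv": observed})
            null_rows.append(
                {"layer": layer, "index": index, "null_cv_mean": mean, "null_cv_sd": sd}
            )
    overall_cvs = pd.DataFrame(overall_rows)
    null_stats = pd.DataFrame(null_rows)

    ttest_rows = []
    for i, a in enumerate(layers):
        for b in layers[i + 1 :]:
            for index in indices:
                cv_a = overall_cvs.query("layer == @a and index == @index")["cv"].iloc[0]
                cv_b = overall_cvs.query("layer == @b and index == @index")["cv"].iloc[0]
                t, p = cv_ttest(
                    cv_a, nulls[(a, index)][1], cv_b, nulls[(b, index)][1],
                    n_reps=config.n_null,
                )
                ttest_rows.append(
                    {"layer_a": a, "layer_b": b, "index": index, "t": t, "p": p}
                )
    cv_ttests = pd.DataFrame(ttest_rows)

    # --- shared nodes and rank-norm matrices
    shared: dict[str, set[str]] = {}
    rank_norm_matrices: dict[str, pd.DataFrame] = {}
    for layer in layers:
        sub = profiles[profiles["layer"] == layer]
        presence = sub.groupby("node")["group"].nunique().to_dict()
        keep = shared_nodes(presence, min_networks=config.min_shared_networks)
        shared[layer] = keep
        mat = sub.pivot(index="node", columns="group", values="rank_norm")
        mat = mat.reindex(index=sorted(keep), columns=groups)
        rank_norm_matrices[layer] = mat

    node_cvs, node_cv_wilcoxon = node_cv_comparison(rank_norm_matrices)

    # --- cross-validation of ranks between gradient halves
    half = len(groups) // 2
    low_groups, high_groups = groups[:half], groups[half:]
    cross_validation: dict[str, CrossValidation] = {}
    d_by_layer: dict[str, Sequence[float]] = {}
    for layer in layers:
        try:
            cv = cross_validate_ranks(
                rank_norm_matrices[layer], low_groups, high_groups,
                band=config.band, d_metric=config.d_metric,
            )
            cross_validation[layer] = cv
            d_by_layer[layer] = cv.d_values.to_numpy()
        except ValueError as exc:
            soft_errors.append(f"cross-validation {layer}: {exc}")
    d_value_anova = None
    if len([v for v in d_by_layer.values() if len(v) > 1]) >= 2:
        d_value_anova = compare_cv_distributions_anova(d_by_layer)

    # --- pairwise correlation CVs, ANOVA, randomization test
    pair_cvs: dict[str, pd.Series] = {}
    pair_cv_excluded: dict[str, int] = {}
    randomization: dict[str, tuple[float, float]] = {}
    for layer in layers:
        corrs = {g: correlations[(layer, g)] for g in groups}
        cvs, excluded = pairwise_correlation_cv(
            corrs, sorted(shared[layer]), use_abs=config.cv_use_abs
        )
        pair_cvs[layer] = cvs
        pair_cv_excluded[layer] = excluded
        coeffs = pairwise_coefficient_matrix(corrs, sorted(shared[layer]))
        coeffs = coeffs[coeffs.notna().sum(axis=1) >= 2]
        if coeffs.shape[0] >= 2:
            randomization[layer] = correlation_randomization_test(
                coeffs, n_perm=config.n_perm, seed=config.seed, use_abs=config.cv_use_abs
            )
        else:
            soft_errors.append(f"randomization {layer}: too few complete pairs")
    pair_cv_anova = None
    usable = {l: v.to_numpy() for l, v in pair_cvs.items() if len(v) > 1}
    if len(usable) >= 2:
        pair_cv_anova = compare_cv_distributions_anova(usable)

    # --- environment association
    mantel: dict[str, list[MantelResult]] = {}
    bray: dict[str, tuple[dict[int, list[float]], float]] = {}
    env_by_group = {g: metadata.env.loc[grouping.samples_in(g)] for g in groups}
    for layer in layers:
        keep = sorted(shared[layer])
        if keep:
            rn = {
                f"{layer}/{g}": {
                    n: v
                    for n, v in rank_norm_matrices[layer][g].dropna().items()
                }
                for g in groups
            }
            scores = connectivity_scores(rn, keep, [f"{layer}/{g}" for g in groups])
            scores.columns = groups
            abund = {g: filtered[(layer, g)] for g in groups}
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    mantel[layer] = connectivity_environment_association(
                        scores, abund, env_by_group,
                        n_perm=config.env_n_perm, seed=config.seed,
                    )
            except ValueError as exc:
                soft_errors.append(f"mantel {layer}: {exc}")
        bray[layer] = bray_curtis_by_group_difference(tables[layer], grouping)

    return ReportBundle(
        config=config,
        metadata=metadata,
        tables=tables,
        grouping=grouping,
        filtered=filtered,
        correlations=correlations,
        threshold_scans=scans,
        networks=networks,
        topology=topology,
        profiles=profiles,
        overall_cvs=overall_cvs,
        null_stats=null_stats,
        cv_ttests=cv_ttests,
        shared=shared,
        rank_norm_matrices=rank_norm_matrices,
        node_cvs=node_cvs,
        node_cv_wilcoxon=node_cv_wilcoxon,
        cross_validation=cross_validation,
        d_value_anova=d_value_anova,
        pair_cvs=pair_cvs,
        pair_cv_excluded=pair_cv_excluded,
        pair_cv_anova=pair_cv_anova,
        randomization=randomization,
        mantel=mantel,
        bray_curtis=bray,
        soft_errors=soft_errors,
    )


def write_bundle(bundle: ReportBundle, out_dir: str | Path) -> None:
    """Serialize a bundle to TSV/JSON/GraphML files under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mio.write_metadata_tsv(bundle.metadata, out / "metadata.tsv")
    for layer, table in bundle.tables.items():
        mio.write_abundance_tsv(table, out / f"abundance_{layer}.tsv")
    nets_dir = out / "networks"
    nets_dir.mkdir(exist_ok=True)
    for (layer, group), net in bundle.networks.items():
        mio.write_network(net, nets_dir / f"{layer}_{group}")
        bundle.threshold_scans[(layer, group)].candidates.to_csv(
            nets_dir / f"{layer}_{group}_scan.tsv", sep="\t", index=False
        )
    bundle.topology.to_csv(out / "topology.tsv", sep="\t", index=False)
    bundle.profiles.to_csv(out / "node_profiles.tsv", sep="\t", index=False)
    bundle.overall_cvs.to_csv(out / "overall_cvs.tsv", sep="\t", index=False)
    bundle.null_stats.to_csv(out / "null_stats.tsv", sep="\t", index=False)
    bundle.cv_ttests.to_csv(out / "cv_ttests.tsv", sep="\t", index=False)
    if len(bundle.node_cvs):
        bundle.node_cvs.rename("cv").to_csv(out / "node_cvs.tsv", sep="\t")
    for layer, cv in bundle.cross_validation.items():
        df = bundle.cross_validation[layer].points.copy()
        df["d_value"] = cv.d_values
        df.to_csv(out / f"cross_validation_{layer}.tsv", sep="\t", index_label="node")
    for layer, cvs in bundle.pair_cvs.items():
        if len(cvs):
            cvs.rename("cv").to_csv(out / f"pair_cvs_{layer}.tsv", sep="\t")
    mantel_rows = [
        {"layer": layer, "variable": m.variable, "r": m.r, "p": m.p, "n_perm": m.n_perm}
        for layer, results in bundle.mantel.items()
        for m in results
    ]
    pd.DataFrame(mantel_rows).to_csv(out / "mantel.tsv", sep="\t", index=False)

    report = {
        "node_cv_wilcoxon": {f"{a}|{b}": p for (a, b), p in bundle.node_cv_wilcoxon.items()},
        "d_value_anova": bundle.d_value_anova,
        "pair_cv_anova": bundle.pair_cv_anova,
        "randomization": {
            layer: {"observed_mean_cv": o, "p": p}
            for layer, (o, p) in bundle.randomization.items()
        },
        "band_fraction": {
            layer: cv.band_fraction for layer, cv in bundle.cross_validation.items()
        },
        "d_mean": {
            layer: float(np.mean(cv.d_values)) for layer, cv in bundle.cross_validation.items()
        },
        "bray_curtis_trend_p": {layer: p for layer, (_, p) in bundle.bray_curtis.items()},
        "shared_node_counts": {layer: len(s) for layer, s in bundle.shared.items()},
    }
    mio.write_json(report, out / "conservation_report.json")
    manifest = {
        "config": dataclasses.asdict(bundle.config),
        "grouping": bundle.grouping.assignment,
        "n_networks": len(bundle.networks),
        "soft_errors": bundle.soft_errors,
    }
    mio.write_json(manifest, out / "manifest.json")
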