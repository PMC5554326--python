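# Methods

This note records the models behind `menconserve`, the parameter choices
that matter, what the synthetic generator does and does not emulate, and
the numerical decisions taken where the underlying procedures are
conventionally under-specified.

## The analysis in one paragraph

Feature-by-sample abundance tables from several "layers" (one species-like,
one or more trait-like) are analyzed along an environmental gradient.
Samples are grouped into contiguous gradient windows; each (layer, group)
yields one co-occurrence network via prevalence filtering (> 50% detection),
per-feature standardization, Pearson correlation, and an adjacency cutoff
chosen by the random-matrix-theory (RMT) criterion. Structural conservation
across windows is measured by coefficients of variation (CV) of overall
topology indices and of per-node normalized connectivity ranks, with
degree-preserving null ensembles, rank-sum/ANOVA comparisons between
layers, a column-randomization test for pair-correlation conservation, and
Mantel tests linking topology to environmental variables.

## Synthetic data generator

The generator emulates a 40-sample survey across pH 1.86–4.10 with six
a-priori groups of 6–8 samples and 14 environmental covariates whose
population correlations with pH are configurable (conductivity and
dissolved metals negative, dissolved oxygen positive, etc.). pH values are
drawn uniformly, the endpoints pinned, and samples sorted, so every group
is populated.

Each feature follows one of five response archetypes:

| archetype | curve | default parameters |
|---|---|---|
| `linear_up` | β(pH − c), c below the gradient | slope β ∈ U(0.5, 2), anchor c 0.3–1.2 gradient-spans below pH_min |
| `linear_down` | β(c − pH), c above the gradient | mirror image |
| `unimodal` | Gaussian bump in pH | optimum ∈ gradient, width 0.4–0.8 spans |
| `log_unimodal` | Gaussian bump in log pH | width 0.3–0.6 log units |
| `stochastic` | smooth stationary random curve in log abundance | 8 spline knots, amplitude U(0.5, 1.2) |

Two design points deserve emphasis.

**Linear anchors and bump widths are chosen for near-constant relative
steepness.** The conservation analysis depends on features correlating
*within* a narrow gradient window (6–8 samples spanning ≈ 0.4 pH units).
A feature's within-window signal-to-noise is its relative slope times the
window's pH spread over its residual noise; anchoring linear responses
just outside the gradient keeps that ratio roughly constant across
windows, which is what lets a deterministic feature hold a similar network
position in every group.

**The stochastic archetype fluctuates; it is not white noise.** A
stochastic feature follows a smooth random curve along the gradient, so it
co-varies genuinely with its neighbors inside any one window while its
correlation partners change from window to window. Independent noise would
instead make every true pair correlation zero in all windows — a pattern
that is perfectly "conserved at zero" and inverts the species-vs-trait
contrast the generator is meant to produce. The incidental linear
component of each curve is damped by 75% so that, in aggregate, stochastic
features carry no systematic pH trend (mean |Pearson r| with pH below 0.2
across features) yet retain a residual low-frequency part, as sporadically
pH-tracking taxa do.

Observed abundances multiply the archetype expectation by mean-one
lognormal noise. The noise level is per-feature: a base coefficient of
variation (`noise_cv`) scaled by a lognormal factor with log-sd 1.0
(`noise_heterogeneity`). This heterogeneity gives deterministic features a
reproducible hierarchy of correlation strength — hence of connectivity —
rather than an exchangeable block whose internal ordering would be pure
noise.

Zeros enter by two routes. A detection limit zeroes each feature's lowest
`detection_quantile` of *systematic* abundance, so non-detection is
contiguous along the gradient (a feature is absent from the part of the
gradient where it is rare); and a sporadic per-feature dropout rate
(lognormal around `dropout`, capped at 0.9) zeroes cells independently.

Layer presets fix the study conditions:

- **species-like**: 15% linear (split up/down), 15% unimodal, 70%
  stochastic; `noise_cv` 0.3; dropout 0.45; no detection quantile. The
  heavy sporadic dropout reproduces the collapse of the shared-node set
  (a few dozen nodes present in > 3 of 6 networks out of 200 features),
  and the high noise makes even the deterministic minority weakly
  predictable — species trends exist but are noisy.
- **trait-like**: 40% linear, 30% unimodal, 10% log-unimodal, 20%
  stochastic; `noise_cv` 0.05; dropout 0.05; detection quantile 0.30.

These mixtures implement the qualitative claim that a higher proportion of
traits than species respond deterministically; the exact percentages are
modeling choices exposed in `LayerSpec`, not estimates from data. A
`latent_amplitude` knob can add a shared smooth secondary-driver factor
(metal concentrations co-varying with but not determined by pH); it
defaults to 0 because any sample-level global structure is, by
construction, statistically identical across randomly composed groups and
therefore *stabilizes* the random-grouping control rather than serving it.

What the generator does **not** emulate: read-level sequencing artifacts,
compositional closure (tables are raw positives, not simplex-constrained),
probe cross-hybridization, phylogenetic correlation between features, and
spatial/site autocorrelation beyond the gradient itself. Tests passing on
this generator show the pipeline's statistics behave as designed under the
stated response-type regime; they are not evidence about any particular
real community.

## Network construction

- **Prevalence**: "detected" means value strictly > 0; "more than half"
  is strict (4 of 8 samples fails).
- **Standardization** uses the sample standard deviation (n − 1);
  zero-variance features are dropped with a warning.
- **RMT threshold scan**: candidates run 0.30–0.99 in steps of 0.01. At
  each candidate the matrix is thresholded (|r| < t zeroed, unit diagonal),
  its eigenvalues unfolded, and the nearest-neighbor spacing distribution
  tested by chi-square (equal-width bins over [0, 3] mean spacings, bin
  count ≈ n/8 clamped to [5, 25]) against the Poisson density e^−s and the
  Wigner/GOE surmise (πs/2)e^(−πs²/4). The chosen threshold is the
  smallest candidate whose Poisson fit is accepted (p > 0.05) *and* beats
  the GOE fit. A `consecutive` option can require the acceptance to hold
  for several successive candidates.
- **Unfolding** maps eigenvalues through a Gaussian-kernel-smoothed
  integrated spectral density (monotone by construction). The bandwidth is
  Silverman's rule with the scale taken as min(sd, IQR/1.34): thresholded
  similarity matrices carry a few very large module eigenvalues that would
  otherwise inflate the smoothing scale far beyond the bulk spacing scale.
  Numerically degenerate eigenvalues (spacing < 1e−8) are collapsed first;
  candidates with fewer than 20 distinct spacings are skipped.
- **Fallback**: with 6–8 samples and ≤ a few hundred features a scan
  occasionally never formally accepts. `rmt_threshold(..., on_fail="best")`
  (used by the pipeline) then takes the usable candidate with the best
  Poisson fit that still beats GOE, or failing that the most spacing-rich
  candidate, with a warning; the strict variant raises instead.
- **Adjacency**: |r| ≥ t links the pair, the signed r is kept as the edge
  weight annotation, isolated nodes are dropped. All topology statistics
  are computed on the simple unweighted graph.

## Topology and ranks

avgGD averages shortest-path lengths over mutually reachable pairs only
(thresholded networks are routinely disconnected). avgCC counts degree-<2
nodes as 0. Modularity is greedy agglomerative (Clauset–Newman–Moore, via
networkx) with Newman–Girvan Q on the unweighted graph.

Connectivity ranks use rank 1 = most connected with average ranks for
ties; Max is the maximum rank in the network and
Rank_norm = (1 − (Max − Rank_org)/(Max − 1))·99 + 1. This direction is the
only one under which the connectivity score 101 − Rank_norm puts hubs at
100, as the score's interpretation requires. With ties at the top, the
hub's average rank exceeds 1 and no node attains Rank_norm = 1 exactly;
the bounds 1 and 100 are attained whenever the extreme ranks are
untied (e.g., any network with a unique hub).

## Conservation statistics

- CV is the sample standard deviation (n − 1) over the mean; it is
  undefined at zero mean.
- **Null ensembles**: replicate k rewires every group's network
  independently (Maslov–Sneppen double-edge swaps, 100 × n_edges attempts,
  rejecting self-loops and duplicates; seeds derived from (master, group,
  k)) and contributes one across-group CV per index; 100 replicates by
  default. The layer comparison is a Welch t-test using the ensemble
  standard deviations with n = replicates.
- **Shared nodes**: strictly more than 3 networks (of 6).
- **Cross-validation**: x = mean normalized rank over the low-gradient
  half (G1–G3), y over the high half (G4–G6); D = |x − y|/√2
  (perpendicular distance to the diagonal; a plain |x − y| variant is
  configurable since printed summaries cannot disambiguate the two); the
  band fraction counts nodes with |x − y| strictly below 20 rank units.
- **Pair CVs and the randomization test** operate on coefficient
  magnitudes |r| by default (`cv_use_abs`). Pairs whose correlation flips
  sign along the gradient — the species layer's hallmark — have signed
  means near zero and unstable signed CVs; magnitudes keep the dispersion
  measure comparable between layers. The signed variant remains available.
- **Randomization test**: each permutation shuffles every column (group)
  independently and recomputes the mean row-CV; p = (1 + #{null ≤
  observed})/(n_perm + 1), one-sided toward conservation, 999 replicates
  by default (minimum attainable p = 0.001). Missing cells are allowed:
  the missingness mask is fixed and each column's observed entries permute
  among their own positions, which reduces to the textbook test on
  complete matrices. Rows need ≥ 2 observed values and a mean above
  tolerance.
- **Mantel tests** run through scikit-bio (Pearson on condensed upper
  triangles, simultaneous row/column permutations, one-sided positive,
  add-one correction, seeded); 999 permutations by default.

## Problem sizes and the desk-scale regime

The bundled analyses run at 100–200 features per layer, 40 samples, six
groups, with permutation counts reduced in examples and tests (null
ensembles 4–30, randomization 199, Mantel 99–199); these sizes keep a full
pipeline run in minutes on one core while leaving every statistic
well-defined. Three desk-scale behaviors are worth knowing:

- With 6–8 samples per group, pairwise correlation estimates carry large
  sampling noise; layer contrasts are therefore asserted on pooled
  distributions or as directional trends over several generator seeds
  rather than on single-run p-values.
- In the random-grouping control (the same trait layer analyzed under
  shuffled group membership), the modularity CV robustly increases —
  randomly composed groups churn the prevalence-filtered feature sets, and
  that churn expresses in module structure — but the avgGD CV is flat and
  the avgCC CV tends the other way at this scale: with so few samples per
  group those indices' variation is dominated by correlation-estimator
  noise, which random mixing does not inflate.
- No shared node is typically prevalence-present in all six groups, which
  is why the randomization test tolerates missing cells.

## Known limitations

- The RMT criterion has limited power on matrices with fewer than ~100
  retained features; the chosen threshold can vary by several hundredths
  between otherwise similar groups, and the `on_fail="best"` fallback is a
  pragmatic rather than principled choice.
- Conclusions about conservation are conditional on the degree-preserving
  null model; other null families (configuration sampling, spectral nulls)
  are out of scope.
- CV-based conservation measures are scale-dependent near small means:
  hub ranks (near 1) show inflated CVs relative to peripheral ranks (near
  100) for equal absolute jitter. Comparisons are always between layers
  under the same convention, which cancels the bias to first order.
- The generator's presets are stylized study conditions, not fitted
  parameters; absolute values of CVs, D-values or band fractions at desk
  scale are not comparable to any particular survey's.
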