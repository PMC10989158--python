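# Methods

This note documents the models, conventions and numerical choices behind
`soilwebdex`, in the order the pipeline applies them.

## Enzyme profile indices

**Standardization.** Each enzyme column is divided by its maximum over
*all* samples in the table and multiplied by 100, so every column peaks
at 100. The maximum is taken over the whole data set (both treatments,
both seasons); callers wanting per-stratum scope must split the table
first. Standardization removes the order-of-magnitude differences
between enzymes (oxidase activities run ~10–100× hydrolase activities)
before any profile-level aggregation. It is scale-invariant: multiplying
a raw column by a constant leaves all standardized quantities unchanged.

**Ratio indices** (BG:NAG, BG:PHOX, NAG:LAP) are computed on **raw**
activities by default: they are activity ratios in the
enzymatic-stoichiometry literature and a per-column rescaling would
change their values meaninglessly. `ratios_on="standardized"` is
available for sensitivity analysis. A zero denominator yields a missing
value with a logged warning, never an exception.

**Shannon diversity** uses standardized activities, renormalized within
the chosen sub-profile: the standardization exists precisely to make the
eight enzymes commensurable, and diversity of the raw profile would be
dominated by the oxidases. The raw-scale alternative is available by
computing `shannon()` on the raw table directly. Sub-profiles resolve by
enzyme class: *whole* (all), *C-degrading* (C-hydrolases + oxidases),
*hydrolase* (C- + N-hydrolases), *C-hydrolase*. Zero activities
contribute 0 (the $p\ln p \to 0$ limit). Enzyme richness is deliberately
not computed: with eight common enzymes detected in every sample it is
constant by construction.

**Composition** converts standardized activities to per-sample
proportions, then applies Bray–Curtis + PCoA and reports PCo1.

## Ordination

Bray–Curtis dissimilarity is computed by `scipy.spatial.distance`;
classical PCoA by double-centering ($G = -\tfrac12 J D^2 J$) and
symmetric eigendecomposition. Axes with non-positive eigenvalues
(Bray–Curtis matrices are generally non-Euclidean) are dropped from the
coordinates without Lingoes/Cailliez correction — the minimal choice,
and the dropped axes carry no usable coordinates anyway. The full
eigenvalue spectrum is retained on the result object for inspection.

**Axis sign convention.** A PCoA axis is defined only up to sign. Each
axis is oriented so its largest-magnitude coordinate is positive, ties
broken by the earliest sample. This matters: the whole-community
composition index is the *average* of four per-group PCo1 vectors, and
correlations against PCo1 change sign (not magnitude) with orientation.
Any fixed convention is equally valid; this one is deterministic and
label-independent. The test suite cross-checks eigenvalues and
coordinate magnitudes against scikit-bio's PCoA.

## Food-web metrics

**Rarefaction** is a single multivariate-hypergeometric draw per sample
(subsampling without replacement) at a common depth, deterministic given
the seed — not a mean over repeated draws, which would produce
non-integer counts. Depth defaults to the minimum sample total per
group; nematodes default to 100 individuals, the standard floor for
faunal diversity indices. Nematode analyses first drop herbivores: only
the free-living trophic groups (bacterivores, fungivores,
omnivore–predators) belong to the decomposer web.

**Alpha diversity**: richness = taxa with count > 0; $H'$ in nats;
Pielou $J = H'/\ln(\text{richness})$, missing when richness is 1.

**Channel indices**: NCR = B/(B+F) on rarefied free-living counts;
NCI = 100·0.8 Fu₂/(3.2 Ba₁ + 0.8 Fu₂) with Ba₁/Fu₂ the bacterivorous
cp-1 and fungivorous cp-2 abundances; PCI = fungivore:bacterivore
relative abundance among protozoa, with "other" feeding habits excluded
from both sides; F:B = fungal/bacterial rRNA gene copies. All are
invariant to rescaling the count table; boundary cases (no fungivores,
no bacterivores) give the documented boundary value or a missing value.

**Whole-community aggregation**: each group's metric is z-scored across
samples (n−1 denominator) and the four z-scores averaged. A group with
zero variance contributes zeros — it carries no contrast, and dropping
it would silently reweight the remaining groups. Community sizes come
from the substrate-style table (gene copies for bacteria/fungi, direct
abundances for protozoa/nematodes) because sequence counts are
compositional and carry no size information.

## Co-occurrence networks

**Screen.** Spearman correlations between all feature pairs; an edge
requires $|\rho| > 0.6$ *and* $p < 0.05$. Because networks are built per
treatment at n = 8, the t-approximation for Spearman p-values is
unreliable; for $n \le 9$ (tie-free) the p-value comes from the exact
permutation null of the rank statistic (n! permutations, cached per n).
Ties, or larger n, use the t-approximation on average ranks. No
multiple-testing correction is applied by default (the screen is defined
by raw cutoffs); FDR is available as an option in the association layer.
Features with zero variance or nonzero prevalence below half the samples
are dropped first — at n = 8, zero-inflated features otherwise generate
spurious perfect correlations.

**Complexity.** avgK = 2L/N; avgCC = mean local clustering with
degree < 2 nodes contributing 0; GD = mean unweighted shortest-path
length over reachable ordered pairs (unreachable pairs are excluded and
logged; restricting to the largest component is a flag-selectable
alternative); Con = L/C(N,2); modularity from networkx's deterministic
greedy modularity maximization — chosen over Louvain/Leiden because it
needs no seed, so module counts and Zi–Pi roles are exactly
reproducible. A module is a community with ≥ 2 nodes. Edge signs are
kept for link accounting only; all path-based metrics treat the graph as
unweighted and unsigned.

**Stability.** Robustness: remove ⌊0.5 N⌋ uniformly chosen nodes and
score the fraction of *surviving* nodes that retain at least one edge;
the mean over 100 repetitions (seeded) is reported. The alternative
reading — relative size of the largest connected component — is not the
headline metric here. Vulnerability: with global efficiency
$E = \frac{1}{N(N-1)}\sum_{u \ne v} 1/d(u,v)$, each node's contribution
is $V_i = (E - E_{-i})/E$ with $E_{-i}$ recomputed on the remaining
N−1 nodes; the maximum over nodes is reported. Both estimator and
efficiency are checked against exact enumeration / Floyd–Warshall
oracles in the tests.

**Node roles.** Zi = within-module degree z-score (module sd 0 → Zi 0);
Pi = 1 − Σₘ(k_im/k_i)² (isolated node → 0). Thresholds are strict:
network hub Zi > 2.5 and Pi > 0.62; module hub Zi > 2.5; connector
Pi > 0.62; otherwise peripheral. A node exactly on a boundary is
assigned to the non-hub/non-connector side. Keystones are all
non-peripheral nodes.

## Association layer

Treatment comparisons use Welch's t-test by default (safer than pooled
variance at 4 samples per treatment × season cell); Student's pooled
test is a flag. Percent change is reported relative to the declared
baseline level (first level in sorted order unless given). Pearson
correlations use pairwise deletion of missing values and require n ≥ 3;
significance is per-cell at α = 0.05 with optional Benjamini–Hochberg.
The panel function evaluates only a declared list of
(index, feature) pairs — the default pairing mirrors the hypothesized
correspondences — leaving all other cells blank rather than fishing
through every combination.

## Synthetic data generator

The generator is a testing harness that reproduces the *statistical
shape* of the target study design, not soil biology. Design:
2 treatments × 2 seasons × 4 plots (n = 16).

* **Substrate pools** are lognormal around literature-scale baselines
  (TOC 6.7 g kg⁻¹, TN 1.07 g kg⁻¹ under the arable condition) with
  natural:arable multipliers matching the restoration responses of the
  target system (TOC ×1.929, DOC ×1.634, CKMnO₄ ×1.509, TN ×1.332,
  DN ×1.267); community sizes likewise (bacteria ×1.837, fungi ×2.452,
  protozoa ×1.588, nematodes ×2.401), with an extra ×1.33 fungal channel
  shift so F:B rises under restoration.
* **Communities** are Dirichlet-multinomial: a fixed lognormal base
  composition per group, a fixed per-treatment composition offset, a
  flattening exponent (1.5) that raises evenness/richness under the
  natural treatment, and a per-sample fungivore↔bacterivore tilt driven
  by the standardized log F:B latent. Nematode guild-level shares are
  fixed (bacterivore 0.40, fungivore 0.25, omnivore–predator 0.15,
  herbivore 0.20, before tilt) so free-living counts stay safely above
  the 100-individual rarefaction floor at the configured depths. cp
  classes and feeding habits are taxon traits, fixed at generation.
* **Enzyme activities** are log-linear in the latent signals:
  a common term 0.5·(0.6 z(log TOC) + 0.4 z(log abundance)) drives gross
  activity; NAG/LAP load ±0.35 on z(log F:B) so NAG:LAP tracks the
  channel; BG loads −0.35 on z(log TOC:TN) and +0.35 on
  z(log CKMnO₄:TOC); the per-enzyme spread shrinks with the community
  diversity latent (rate 0.5) so profile evenness tracks community
  Shannon; residual lognormal noise sd 0.15. All coefficients are
  recorded in `ground_truth`.

Defaults (`paper-like`): 300/150/100/25 taxa and 5000/4000/3000/200
depth for bacteria/fungi/protozoa/nematodes. The `paper-like-small`
preset (60/40/30/20 taxa, 2000/1500/1000/200 depth) is the same
condition at reduced size, used for repeated-simulation experiments; the
`null` presets zero every coupling and multiplier for calibration
checks.

What the generator does **not** emulate: phylogenetic or spatial
structure, seasonal autocorrelation beyond a fixed offset,
compositional-bias artifacts of sequencing, or taxon-specific enzyme
production. Passing recovery tests therefore show the *estimators and
screens are correct and calibrated under the assumed generative shape*,
not that the indices will correlate in any real soil.

## Numerical conventions

Natural logarithms throughout. Missing values are NaN in memory, empty
fields on disk; index tables are written with `%.17g` and read with
round-trip float parsing, so write→read is bit-identical. Samples are
always matched by `sample_id`, never row order. All stochastic steps
(rarefaction, robustness, generator) take explicit integer seeds; the
pipeline's manifest records parameters and input checksums, and rerunning
with the same config is bitwise reproducible.

## Problem sizes used in the verification scripts

The acceptance script uses: 1000 repetitions for the star-graph
robustness estimate, 200 simulated 8×10 tables for screen calibration,
500 reduced-size bundles for recovery power, 200 null bundles for
calibration, 100 planted two-block tables for module recovery, and two
full pipeline runs for the determinism check — sizes at which the
Monte-Carlo error bands quoted in the tests are meaningful.
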