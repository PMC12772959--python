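# Methods

`spatmap` reconstructs the spatial positions of dissociated single-cell or
single-nucleus transcriptomes by comparing each cell's expression of a
curated landmark-gene panel with the binary landmark signatures measured by
in situ sequencing (ISS) on a reference tissue section. This note records
the model, the numerical choices, and what the synthetic validation does
and does not establish.

## Spatial reference: binned landmark signatures

ISS output is a spot table — one `(gene, x, y)` record per detected
transcript in a fixed pixel reference space. Spots are aggregated into
square tiles (default 16 px; origin top-left, x = column, y = row, 0-based,
half-open tiles `[k·tile, (k+1)·tile)`). Partial edge tiles are retained,
so a 16,619 × 14,810 px space yields ⌈14810/16⌉ × ⌈16619/16⌉ = 926 × 1039
bins. Reads on or beyond the maximum boundary are rejected rather than
clamped, which avoids silently inflating the edge tiles. Each bin's
signature is the bit vector of landmark presence (presence/absence, not
counts; a count mode exists but the model does not use it). Identical
signatures are deduplicated; all downstream likelihood work is done once
per unique signature and broadcast to the bins that carry it.

## Expression model

Droplet-derived log-expression is sparse and zero-inflated, which defeats
direct Gaussian modelling. We smooth profiles with a t-step random walk on
a cell–cell affinity graph: symmetric kNN Gaussian kernel with adaptive
bandwidth (each cell's scale is the distance to its k-th neighbour),
symmetrized by averaging, row-normalized, applied `t` times. Defaults
`n_neighbors = 15`, `t = 3`; `t = 0` is the identity. This is a minimal
diffusion imputation in the spirit of MAGIC-style smoothing; it is a
first-class implementation, exposed and tested on hand-built operators.

Each landmark's imputed expression is fitted with Gaussian mixtures for
k ∈ {2,…,8} (EM, 5 restarts per k, tolerance 1e-6, variance floor 1e-6) and
the k with maximum achieved log-likelihood is selected — raw likelihood,
not a penalized criterion. Candidate k whose EM fails to converge after
the restarts are skipped with a warning; it is an error only if no k
converges. Because raw likelihood selection tends to over-segment a broad
expressing population, the fitted components are reduced to an on/off
dichotomy by splitting at the **largest gap between sorted component
means**: the upper group is the expressing ("on") population, the lower
group the "off" population, and each group is pooled into a single normal
by moment matching (weighted mean; variance = weighted second moment minus
squared pooled mean). When the expressing population is a single
component, this reduces exactly to "on = the highest-mean component, off =
the pooled rest". Landmarks with no reads in the dissociated data are
excluded with a warning.

## Mapping matrix

Each unique signature defines a diagonal multivariate normal over landmark
expression: marginal mean/variance are the on parameters where the bit is
set and the pooled off parameters where it is not. Scoring every cell
against every unique signature gives a cells × signatures log-density
matrix. Each signature's column is normalized over cells with
**sparsegen-lin** — `sparsemax(z / (1 − λ))`, the Euclidean projection onto
the probability simplex after a sparsity-controlling rescale — yielding a
proper, sparse distribution over cells per bin (softmax would give full
support). Choices the source method leaves open, recorded in config:

- sparsegen-lin operates on log-densities (the same score softmax would
  receive); raw densities underflow across a dozen or more landmarks.
- λ = 0.9 by default. With realistic log-density spreads the projections
  are extremely sparse (often one cell per signature); λ only sharpens
  this further. Columns remain exactly column-stochastic.
- Numerical stability: each column is shifted by its maximum *after* the
  1/(1 − λ) scaling; sparsemax is shift-invariant, so the projection is
  unchanged.

P is stored compactly as the cells × unique-signatures block plus the
per-bin signature index; columns of bins sharing a signature are identical
by construction.

## Projection, smoothing, thresholding

A per-cell feature f (gene expression, 0/1 annotation indicator, regulon
or gene-set score) projects to the per-bin expectation Σ_c P[c,i] f[c] —
linear in f, bounded by min/max of f. Because bins are scored
independently, the field is piecewise constant per signature; a Gaussian
filter (default σ = 1 bin, reflective boundary) suppresses this
high-frequency structure. Thresholding produces virtual in situ images:
either at a percentile of the *nonzero* field values (zeros dominate
sparse fields and would collapse percentiles), or automatically from the
elbow of the sorted unique nonzero values — straight lines are fitted to k
consecutive values starting at the median index and to the k largest
values, and the threshold is the value nearest the lines' intersection
(k = 20 default; a `smallest` anchor variant starts the lower window at
index 0). Masks use a ≥ comparison, so ties can push cardinality above
nominal. Thresholds with nearly parallel fitted lines are an error
suggesting a larger k.

## Evaluation

Reconstruction fidelity compares the measured landmark distribution (its
detected bins, uniform weights) with the model field for the same
landmark, binarized at the **measured cardinality** (top-n bins after
smoothing; ties broken lexicographically by (row, col)). Distance is the
debiased Sinkhorn divergence

S_ε(a,b) = OT_ε(a,b) − ½OT_ε(a,a) − ½OT_ε(b,b),

with cost = half squared Euclidean bin distance and ε = blur², blur = 2
bins by default. The solver is a log-domain Sinkhorn with ε-scaling.
Stopping is declared on dual-value stability rather than on the
potentials: when the point spread far exceeds the blur, the potentials
equilibrate arbitrarily slowly across nearly disconnected blocks while the
value and marginals have converged. Self-terms use the damped symmetric
iteration (the alternating update oscillates on symmetric problems).
Identical inputs short-circuit to S = 0 exactly. Two modes exist:
`exact` (iterate to a 1e-9 dual-value tolerance; used for oracle
comparisons) and `fast` (a fixed annealing schedule, one iteration per
ε-stage plus ten at the target; accurate to a few tenths of a percent and
an order of magnitude faster; used for bootstrap statistics, where the
error is far below the spread of the null).

Significance is a spatial bootstrap: for each landmark, 1000 uniform
samples of bins (cardinality-matched, drawn without replacement) are
compared with the measured distribution, and the lower tail mass of the
null divergence distribution at the observed divergence estimates the
probability of the reconstruction arising by chance (threshold 0.05 per
landmark, no multiplicity correction). Replicates share the measured
target, so the solve is batched over replicates in float32 chunks. An
alternative `fixed-size` mode draws a constant sample size irrespective of
cardinality. Generalization uses leave-one-out cross-validation: each
landmark's field is predicted from a mapping rebuilt without that
landmark's bit. The other landmarks' on/off models do not depend on the
exclusion and are fitted once; one null per landmark serves both the
full-model and LOOCV tails. These are computation-sharing choices only.

## Bayesian cluster marking

Whether a transcriptional cluster is "marked" by a gene is estimated from
the gene's imputed expression x_j with per-cell likelihood
x_j ~ Normal(μ_{c(j)}, σ_{c(j)}). The cluster means carry a two-population
hierarchical prior, μ_k ~ ½N(m_off, s_m²) + ½N(m_on, s_m²) with
m_on > m_off, whose induced Bayes decision boundary is exactly a logistic
rule: the marking probability of cluster k is logistic(α(μ_k − T)) with
threshold T = (m_on + m_off)/2 and sharpness α = (m_on − m_off)/s_m². A
model with free (T, α) and purely prior-driven values cannot learn a
decision boundary from data — the likelihood does not touch them — so the
hierarchical construction is used instead; it reproduces the logistic
marking rule while making T and α identified. Hyper-priors: m_off, m_on ~
N(mean, SD) of all-gene expression; cluster SDs get a positive Cauchy
prior located/scaled by the median and MAD of the per-gene SDs; s_m gets a
log-normal prior anchored at twice the median standard error of a cluster
mean. The s_m prior must be proper and informative: with few clusters the
mixture scale is degenerate (the likelihood is unbounded as s_m → 0 when
components interpolate the means exactly, while a broad one-population
mode wins on posterior volume).

Sampling is componentwise adaptive random-walk Metropolis (proposal scales
initialized at the known posterior scales, Robbins–Monro adaptation to
0.44 acceptance during a 50% warm-up), 4 chains, thinned ×5; cluster-level
sufficient statistics make one posterior evaluation O(J). Split-R̂ is
checked on the identified parameters (μ_k, log σ_k) with limit 1.05; T and
α may be legitimately multimodal when clusters are not separated (their
uncertainty is what widens the credible intervals), so they are not
gated. Summaries are posterior means and equal-tailed credible intervals
(default 89%).

## Ligand–receptor inference

Complex expression obeys stoichiometry: per cell, the minimum across
component genes (applied to both receptor and ligand complexes).
Projecting complex expression through P gives spatial abundance
distributions; bins below a mass floor (1e-8) are dropped, and for
tractable transport the support can be truncated to the top-mass bins
covering 99.9% of mass (cap 512 by default; discarded mass is not
redistributed). Ligand mass moves toward receptor sites by unbalanced
entropic optimal transport with KL-relaxed marginals of strength
ρ = reach²/2: transported mass between locations at distance d decays as
exp(−d²/(2·reach²)), so ligand farther than a few reach lengths from any
receptor stays untransported. The solver anneals ε and stops on stability
of the received-mass vector (the plan, unlike the potentials, is invariant
under the slowly equilibrating translation mode). Per-receptor-bin
received mass and saturation = min(received/receptor mass, 1) come from
the plan's column sums. Interactions are ranked by
(mean ligand abundance × mean receptor abundance) × exp(−S/reach²), with
S the debiased Sinkhorn divergence between the two spatial distributions;
the composite is one documented choice and every raw term is reported so
users can re-rank. Interactions with missing components are skipped with a
warning; zero-abundance interactions score 0 and rank last.

## Synthetic tissue

The generator produces the full data triplet — ground-truth cell table,
ISS spot table, and matched dissociated profiles with shuffled rows — so
every stage is testable without downloads. Default study conditions (all
configurable):

- Reference space 1024 × 1024 px, 16 px tiles → 64 × 64 bins. 1200 cells
  placed uniformly; zone membership is taken at bin resolution (the
  resolution at which mapping is evaluated).
- Geometry: four compact equal-area concentric rings (~6% of the space
  each) around the centre plus the remaining ~72% as the outermost zone.
  Compact marked zones keep measured landmark distributions far from
  spatial uniformity — that distance is precisely what gives the uniform
  bootstrap null its discriminating power; zones that tile the whole
  space (especially outer annuli, whose area profile approaches that of a
  uniform sample) make the null unable to distinguish even a perfect
  reconstruction.
- 6 cell types, 12 landmarks: the four ring zones each host one marked
  type (three type-specific landmarks apiece, on-probability 0.9,
  off-target "leak" 0.005), the outer zone hosts an unmarked resident
  type, and an unmarked background type mixes into every zone at 15% —
  emulating cell states outside the curated panel. Three markers per type
  means holding one out for LOOCV still leaves two.
- A cell's own markers switch together through one latent "program" draw
  (comonotone coupling; marginal probabilities unchanged). Independent
  per-gene switching produces cells expressing a single stray marker of
  their type; such a cell is indistinguishable from background once that
  marker is held out and, being the best "all-off" match, paints the
  entire background with its high held-out expression.
- Expression: on ~ N(4.0, 0.8), off ~ N(0.3, 0.25) on the log scale,
  plus N(0, 0.25) measurement noise; optional zero-inflation exercises
  the imputation path. ISS: five candidate spots per expressed landmark,
  each detected with probability 0.5, jittered by N(0, 3 px) around the
  cell.
- A striped geometry (`communication_spec`) supports signaling
  experiments: receptor complex in stripe 0, a "true" ligand in the
  adjacent stripe, a decoy ligand of equal abundance in the distant
  stripe; receptors are slightly scarcer than ligand so saturation is
  meaningful.

What the synthetic tissue does **not** emulate: realistic optics or
barcode chemistry, segmentation errors, ambient RNA, batch effects,
doublets, realistic count-based noise (noise is Gaussian on log scale), or
continuous differentiation gradients — zones and types are discrete.
Passing tests therefore demonstrate the statistical machinery recovers
planted structure under the model's own assumptions at workstation scale;
they do not certify performance on real sections.

## Problem sizes and determinism

Desk-scale defaults: 1200 cells, 64 × 64 bins, 12 landmarks, 1000
bootstrap replicates, 2000 posterior draws; "paper mode" raises bootstrap
replicates and posterior draws to 10,000. All randomness flows through
explicit seeds; identical config + seed reproduces every artifact to
1e-9 (floating) or bitwise (integer). The CLI writes a JSON manifest per
stage (parameters, input checksums, seed, version) and skips stages whose
manifest and outputs are unchanged.

## Known limitations

- Diagonal covariance between landmarks; no cell-count deconvolution per
  bin (each bin's distribution describes one representative cell).
- Raw-likelihood k selection usually saturates the upper bound of the k
  range; the largest-gap on/off reduction absorbs this, but k itself
  should not be interpreted.
- The composite interaction score and the reach→ρ calibration are
  documented choices, validated against qualitative properties (mass
  beyond reach is not moved; co-localized pairs outrank distant ones),
  not against a closed-form standard.
- With λ = 0.9 the mapping is near-one-hot per signature: fields are
  piecewise constant and a minority of cells carry all the mass. This is
  the intended sparse-support behaviour but limits per-cell position
  estimates for unselected cells.
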