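# spatmap

Probabilistic mapping of dissociated single-cell / single-nucleus
transcriptomes onto a spatial reference measured by targeted in situ
sequencing (ISS).

Dissociation destroys spatial context: an snRNA-seq experiment tells you
*what* every cell is, but not *where* it was. A targeted ISS panel of a
few dozen landmark genes measures the converse — sparse gene identity at
high spatial resolution. `spatmap` fuses the two. The reference section is
tiled into bins, each carrying a binary landmark *signature*; every cell
is scored against every unique signature with a diagonal multivariate
normal whose per-landmark marginals come from "on"/"off" Gaussian-mixture
fits on diffusion-imputed expression; and each bin's scores are normalized
over cells with sparsegen-lin (a sparsity-controlled Euclidean projection
onto the probability simplex) into a column-stochastic mapping matrix

P ∈ R^(cells × bins),  P[:, i] = sparsegen-lin( log p(x_c | signature_i) / (1 − λ) ).

Any per-cell quantity f — a gene's expression, a cluster annotation, a
regulon or gene-set score — then projects to a *virtual in situ image*
E[f](i) = Σ_c P[c, i] f[c], which can be smoothed and thresholded.
Reconstruction fidelity is quantified with the debiased Sinkhorn
divergence S_ε(a,b) = OT_ε(a,b) − ½OT_ε(a,a) − ½OT_ε(b,b) against
cardinality-matched binarizations, with significance from a uniform
spatial bootstrap and generalization from leave-one-out cross-validation.
Downstream, a Bayesian model assigns each transcriptional cluster a
posterior probability of being *marked* by a gene
(logistic(α(μ_k − T)) under a two-population prior on cluster means), and
ligand–receptor interactions are re-ranked spatially by transporting
ligand mass to receptor sites with reach-limited unbalanced optimal
transport.

Everything is testable offline: `spatmap.synthetic_data` generates full
synthetic tissues (zoned cell types, bimodal landmark expression,
Bernoulli per-spot ISS detections, matched dissociated profiles) with
known ground truth.

## Worked example

```python
import numpy as np
import spatmap as sm
from spatmap.mapping import mapping_from_tissue

spec = sm.TissueSpec(seed=1)                      # 1200 cells, 64x64 bins
tissue = sm.simulate_tissue(spec)
grid = sm.GridSpec(spec.width_px, spec.height_px, spec.tile)
sg = sm.aggregate_reads(tissue.reads, grid, list(spec.landmarks))
print(f"{len(tissue.reads)} reads -> {sg.n_signatures} unique signatures")

imputed = sm.impute(tissue.expr, n_neighbors=15, t=3)
models = sm.fit_all_landmarks(imputed, list(spec.landmarks), seed=0)
P = mapping_from_tissue(imputed, sg, models, lam=0.9)

acc = sm.mapping_accuracy(P, tissue)
print(f"zone mass {acc['mean_zone_mass']:.3f}, "
      f"enrichment over chance {acc['mean_enrichment']:.1f}x")

report = sm.loocv(sg, imputed, models, n_boot=1000, seed=7)
print(f"LOOCV: {(report.tail_prob_loocv < 0.05).mean():.0%} of landmarks "
      f"reconstruct better than spatial chance (p < 0.05)")
```

prints (exact values are seed-dependent):

```
1708 reads -> 51 unique signatures
zone mass 0.551, enrichment over chance 7.2x
LOOCV: 100% of landmarks reconstruct better than spatial chance (p < 0.05)
```

The enrichment line says cells place their mapping mass in their true
tissue zone about seven times more often than area-proportional
chance; the LOOCV line is the held-out analog of reconstruction accuracy —
each landmark's spatial field predicted by a model trained without it,
compared against the measured signal via Sinkhorn divergence and a
1000-replicate uniform bootstrap null.

A command-line pipeline mirrors the library
(`spatmap simulate | bin-reads | fit-model | map | project | evaluate |
loocv | marking | ccc`), exchanging plain-text artifacts plus JSON
manifests in an output directory; re-runs skip unchanged stages.

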