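"""Bayesian probability that a transcriptional cluster is "marked" by a gene.

Given a gene's (imputed) expression x_j in N cells partitioned into J
clusters, the model estimates, per cluster, the posterior probability that
the cluster expresses the gene — i.e. that its mean expression lies above a
latent threshold T, with a logistic (sigmoid) decision boundary of sharpness
alpha:

    x_j ~ Normal(mu_{c(j)}, sigma_{c(j)})
    p_k = logistic(alpha * (mu_k - T))          (marking probability)

T and alpha are identified through a two-population hierarchical prior on
the cluster means: mu_k ~ 1/2 N(m_off, s_m^2) + 1/2 N(m_on, s_m^2) with
m_on > m_off, whose induced Bayes decision boundary is exactly the logistic
rule with T = (m_on + m_off)/2 and alpha = (m_on - m_off)/s_m^2.  Hyper-
priors for the population means come from the mean/SD of expression over
all genes and cells; cluster SDs get a positive-truncated Cauchy prior
parameterized by the median and median absolute deviation of the per-gene
SDs.  The posterior is sampled with adaptive random-walk Metropolis
(componentwise, 4 chains, 50% warm-up) and summarized by posterior means
and equal-tailed credible intervals (default 89%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp

__all__ = [
    "MarkingModel",
    "MarkingSummary",
    "fit_marking_model",
    "marking_probability",
    "summarize_marking",
]


@dataclass
class MarkingModel:
    """Posterior draws for the cluster-marking model of one gene."""

    gene: str
    cluster_labels: list  # order of the k axis
    mu: np.ndarray  # (n_samples, J)
    sigma: np.ndarray  # (n_samples, J)
    T: np.ndarray  # (n_samples,)
    alpha: np.ndarray  # (n_samples,)
    rhat: dict = field(default_factory=dict)
    n_chains: int = 4

    @property
    def n_samples(self) -> int:
        return self.mu.shape[0]

    def marking_probabilities(self) -> np.ndarray:
        """(n_samples, J) marking probability draws."""
        return expit(self.alpha[:, None] * (self.mu - self.T[:, None]))


@dataclass
class MarkingSummary:
    """Posterior mean and credible interval of marking probability per cluster."""

    table: pd.DataFrame  # columns: cluster, mean, lo, hi
    level: float


def marking_probability(mu_k: float, T: float, alpha: float) -> float:
    """logistic(alpha * (mu_k - T)) for one posterior draw and cluster."""
    return float(expit(alpha * (mu_k - T)))


def _split_rhat(chains: np.ndarray) -> float:
    """Split-R-hat of one scalar parameter; chains shape (n_chains, n_draws)."""
    n_chains, n = chains.shape
    half = n // 2
    if half < 2:
        return np.nan
    seqs = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m, n = seqs.shape
    means = seqs.mean(axis=1)
    W = seqs.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W <= 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


class _Posterior:
    """Log-posterior with per-cluster sufficient statistics (O(J) per eval)."""

    def __init__(self, x, cluster_index, J, m0, s0, sig_loc, sig_scale):
        self.J = J
        self.n_k = np.bincount(cluster_index, minlength=J).astype(float)
        self.s_k = np.bincount(cluster_index, weights=x, minlength=J)
        self.ss_k = np.bincount(cluster_index, weights=x**2, minlength=J)
        self.m0, self.s0 = m0, s0
        self.sig_loc, self.sig_scale = sig_loc, sig_scale
        # empirical-Bayes anchor for the population spread of cluster means:
        # twice the median standard error of a cluster mean
        means = self.s_k / self.n_k
        sds = np.sqrt(np.maximum(self.ss_k / self.n_k - means**2, 1e-12))
        self.sm_anchor = max(2.0 * float(np.median(sds / np.sqrt(self.n_k))),
                             1e-6)

    def unpack(self, theta):
        J = self.J
        mu = theta[:J]
        sigma = np.exp(theta[J : 2 * J])
        m_off = theta[2 * J]
        gap = np.exp(theta[2 * J + 1])
        s_m = np.exp(theta[2 * J + 2])
        return mu, sigma, m_off, gap, s_m

    def logp(self, theta) -> float:
        mu, sigma, m_off, gap, s_m = self.unpack(theta)
        u = theta[self.J : 2 * self.J]
        m_on = m_off + gap
        # cell-level Normal likelihood via sufficient statistics
        quad = self.ss_k - 2 * mu * self.s_k + self.n_k * mu**2
        ll = float(
            np.sum(-self.n_k * (u + 0.5 * np.log(2 * np.pi)) - quad / (2 * sigma**2))
        )
        # two-population prior on cluster means
        lo = -0.5 * ((mu - m_off) / s_m) ** 2
        hi = -0.5 * ((mu - m_on) / s_m) ** 2
        lp_mu = float(
            np.sum(logsumexp(np.stack([lo, hi]), b=0.5, axis=0) - np.log(s_m))
        )
        # hyper-priors: population means ~ N(m0, s0); the population spread
        # of cluster means s_m ~ LogNormal(log(anchor), 0.75) anchored at
        # the precision of the cluster means.  A proper, informative scale
        # prior is needed here: with few clusters the mixture scale is
        # otherwise degenerate (the likelihood is unbounded as s_m -> 0 when
        # the components interpolate the means exactly, while a broad
        # one-population mode wins on posterior volume).
        log_sm = theta[2 * self.J + 2]
        lp_h = (
            -0.5 * ((m_off - self.m0) / self.s0) ** 2
            - 0.5 * ((m_on - self.m0) / self.s0) ** 2
            + theta[2 * self.J + 1]  # Jacobian of gap = exp(d)
            - 0.5 * ((log_sm - np.log(self.sm_anchor)) / 0.75) ** 2
        )
        # truncated-Cauchy prior on cluster SDs (log parameterization)
        lp_sig = float(
            np.sum(-np.log1p(((sigma - self.sig_loc) / self.sig_scale) ** 2) + u)
        )
        return ll + lp_mu + lp_h + lp_sig


def fit_marking_model(
    x: np.ndarray,
    clusters: np.ndarray,
    gene: str = "",
    n_samples: int = 10000,
    seed: int = 0,
    prior_data: np.ndarray | None = None,
    n_chains: int = 4,
    rhat_limit: float = 1.05,
) -> MarkingModel:
    """Sample the marking-model posterior for one gene.

    Parameters
    ----------
    x
        Imputed expression of the gene, one value per cell.
    clusters
        Per-cell cluster labels (any hashable values).
    n_samples
        Total retained posterior draws across chains (post warm-up).
    prior_data
        Cells x genes matrix used to set the hyper-priors (mean/SD of all
        values; median/MAD of per-gene SDs).  Defaults to ``x`` alone.
    """
    x = np.asarray(x, dtype=float)
    clusters = np.asarray(clusters)
    if x.shape != clusters.shape:
        raise ValueError("expression and cluster labels must align")
    labels, cluster_index = np.unique(clusters, return_inverse=True)
    J = labels.size
    if J < 2:
        raise ValueError("need at least 2 clusters")
    counts = np.bincount(cluster_index)
    small = labels[counts < 5]
    if small.size:
        raise ValueError(f"clusters with fewer than 5 cells: {list(small)}")

    if prior_data is None:
        prior_data = x[:, None]
    prior_data = np.asarray(prior_data, dtype=float)
    m0 = float(prior_data.mean())
    s0 = float(prior_data.std())
    if s0 <= 0:
        raise ValueError("prior data has zero variance")
    gene_sds = prior_data.std(axis=0)
    sig_loc = float(np.median(gene_sds))
    sig_mad = float(np.median(np.abs(gene_sds - sig_loc)))
    sig_scale = max(1.4826 * sig_mad, 0.5 * sig_loc, 1e-3)

    post = _Posterior(x, cluster_index, J, m0, s0, sig_loc, sig_scale)

    # initial values from empirical per-cluster moments
    mu0 = np.array([x[cluster_index == k].mean() for k in range(J)])
    sd0 = np.array([max(x[cluster_index == k].std(), 1e-3) for k in range(J)])
    # initialize the mean-population mixture from a midpoint split of the
    # empirical cluster means; s_m starts at its prior anchor so chains need
    # not travel far during warm-up
    split = 0.5 * (mu0.min() + mu0.max())
    lo_grp = mu0[mu0 <= split]
    theta0 = np.concatenate(
        [
            mu0,
            np.log(sd0),
            [lo_grp.mean() if lo_grp.size else mu0.min()],
            [np.log(max(mu0.max() - mu0.min(), 0.05 * s0))],
            [np.log(post.sm_anchor)],
        ]
    )
    dim = theta0.size

    thin = 5  # decorrelates the random-walk draws; diagnostics need it
    keep_per_chain = max(n_samples // n_chains, 10)
    warmup = keep_per_chain  # 50% warm-up (in retained-draw units)
    chains_mu = np.empty((n_chains, keep_per_chain, J))
    chains_sigma = np.empty((n_chains, keep_per_chain, J))
    chains_T = np.empty((n_chains, keep_per_chain))
    chains_alpha = np.empty((n_chains, keep_per_chain))

    counts_k = counts.astype(float)
    # proposal scales start near the known posterior scales: sd/sqrt(n) for
    # cluster means, 1/sqrt(2n) for log-SDs, broader for the hyperparameters
    step0 = np.concatenate(
        [
            2.0 * sd0 / np.sqrt(counts_k),
            1.0 / np.sqrt(counts_k),
            [0.1 * s0],
            [0.2],
            [0.3],
        ]
    )
    jitter0 = np.concatenate(
        [sd0 / np.sqrt(counts_k), 0.3 * np.ones(J), [0.05 * s0], [0.05], [0.1]]
    )
    for c in range(n_chains):
        rng = np.random.default_rng(np.random.SeedSequence([seed, c]))
        theta = theta0 + jitter0 * rng.standard_normal(dim)
        step = step0.copy()
        lp = post.logp(theta)
        acc = np.zeros(dim)
        kept = 0
        for it in range(warmup + keep_per_chain * thin):
            for d in range(dim):
                prop = theta.copy()
                prop[d] += step[d] * rng.standard_normal()
                lp_prop = post.logp(prop)
                accepted = np.log(rng.random()) < lp_prop - lp
                if accepted:
                    theta, lp = prop, lp_prop
                    acc[d] += 1
                if it < warmup:
                    # Robbins-Monro adaptation toward 0.44 acceptance
                    step[d] *= np.exp(
                        (float(accepted) - 0.44) / (1 + 0.1 * it) * 2
                    )
            if it >= warmup and (it - warmup) % thin == thin - 1:
                j = kept
                kept += 1
                mu, sigma, m_off, gap, s_m = post.unpack(theta)
                chains_mu[c, j] = mu
                chains_sigma[c, j] = sigma
                chains_T[c, j] = m_off + 0.5 * gap
                chains_alpha[c, j] = gap / s_m**2

    rhat = {}
    for k in range(J):
        rhat[f"mu[{labels[k]}]"] = _split_rhat(chains_mu[:, :, k])
        rhat[f"sigma[{labels[k]}]"] = _split_rhat(np.log(chains_sigma[:, :, k]))
    bad = {p: r for p, r in rhat.items() if np.isfinite(r) and r > rhat_limit}
    if bad:
        raise RuntimeError(
            f"marking model for {gene or 'gene'} did not mix: split-R-hat > "
            f"{rhat_limit} for {bad}; increase n_samples"
        )

    return MarkingModel(
        gene=gene,
        cluster_labels=list(labels),
        mu=chains_mu.reshape(-1, J),
        sigma=chains_sigma.reshape(-1, J),
        T=chains_T.reshape(-1),
        alpha=chains_alpha.reshape(-1),
        rhat=rhat,
        n_chains=n_chains,
    )


def summarize_marking(model: MarkingModel, level: float = 0.89) -> MarkingSummary:
    """Posterior mean and equal-tailed credible interval per cluster."""
    if model.n_samples < 100:
        raise ValueError("need at least 100 posterior samples to summarize")
    if not (0 < level <= 1):
        raise ValueError(f"level must be in (0, 1], got {level}")
    probs = model.marking_probabilities()
    tail = (1 - level) / 2 * 100
    lo = np.percentile(probs, tail, axis=0)
    hi = np.percentile(probs, 100 - tail, axis=0)
    table = pd.DataFrame(
        {
            "cluster": model.cluster_labels,
            "mean": probs.mean(axis=0),
            "lo": lo,
            "hi": hi,
        }
    )
    return MarkingSummary(table=table, level=level)
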