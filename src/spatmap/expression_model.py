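"""Diffusion imputation of dissociated expression and per-landmark on/off
Gaussian-mixture models.

Droplet-based snRNA/scRNA-seq profiles are sparse and zero-inflated, which
defeats direct Gaussian modelling of landmark expression.  A short random
walk over a cell-cell affinity graph (the idea behind MAGIC-style
imputation) smooths each profile toward its transcriptional neighbourhood
and makes a normality assumption tenable.  Each landmark's imputed
expression is then fitted as a Gaussian mixture with k components (k chosen
by maximum likelihood over a range) and reduced to an "on"/"off" dichotomy:
components are split at the largest gap between their sorted means — the
upper group is the expressing ("on") population, the lower group the
non-expressing ("off") one — and each group is pooled into a single normal
by moment matching.  When the on population is a single component this is
exactly "on = the highest-mean component".
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "OnOffModel",
    "OnOffModelSet",
    "build_affinity",
    "impute",
    "fit_on_off",
    "fit_all_landmarks",
]


@dataclass
class ExpressionMatrix:
    """Cells x genes normalized log-expression with optional cluster labels."""

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    clusters: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be 2-D (cells x genes)")
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError("expression shape does not match cell/gene ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def gene(self, gene_id: str) -> np.ndarray:
        try:
            j = self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not in expression matrix") from None
        return self.values[:, j]

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        idx = [self.gene_ids.index(g) for g in genes]
        return ExpressionMatrix(
            self.values[:, idx], self.cell_ids, list(genes), self.clusters
        )


@dataclass(frozen=True)
class OnOffModel:
    """Two-population summary of one landmark's imputed expression."""

    landmark: str
    mu_on: float
    var_on: float
    mu_off: float
    var_off: float
    k_selected: int
    loglik: float

    def __post_init__(self) -> None:
        if not (self.mu_on >= self.mu_off):
            raise ValueError(
                f"{self.landmark}: mu_on ({self.mu_on}) < mu_off ({self.mu_off})"
            )
        if self.var_on <= 0 or self.var_off <= 0:
            raise ValueError(f"{self.landmark}: non-positive variance")


@dataclass
class OnOffModelSet:
    """On/off models for every retained landmark, in fixed panel order."""

    models: dict[str, OnOffModel]
    panel: list[str]  # retained landmarks, order fixed

    def __post_init__(self) -> None:
        if set(self.models) != set(self.panel):
            raise ValueError("model set and retained panel disagree")

    def __len__(self) -> int:
        return len(self.panel)

    def __getitem__(self, landmark: str) -> OnOffModel:
        return self.models[landmark]

    def arrays(self):
        """(mu_on, var_on, mu_off, var_off) vectors in panel order."""
        m = [self.models[g] for g in self.panel]
        return (
            np.array([x.mu_on for x in m]),
            np.array([x.var_on for x in m]),
            np.array([x.mu_off for x in m]),
            np.array([x.var_off for x in m]),
        )

    def subset(self, panel: list[str]) -> "OnOffModelSet":
        return OnOffModelSet({g: self.models[g] for g in panel}, list(panel))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "landmark": g,
                    "mu_on": m.mu_on,
                    "var_on": m.var_on,
                    "mu_off": m.mu_off,
                    "var_off": m.var_off,
                    "k": m.k_selected,
                    "loglik": m.loglik,
                }
                for g, m in ((g, self.models[g]) for g in self.panel)
            ]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "OnOffModelSet":
        models = {
            r.landmark: OnOffModel(
                r.landmark, r.mu_on, r.var_on, r.mu_off, r.var_off,
                int(r.k), r.loglik,
            )
            for r in df.itertuples(index=False)
        }
        return cls(models, list(df["landmark"]))


# ---------------------------------------------------------------------------
# Imputation


def build_affinity(values: np.ndarray, n_neighbors: int = 15) -> np.ndarray:
    """Row-stochastic diffusion operator from a symmetric kNN affinity.

    Gaussian kernel with adaptive bandwidth (each cell's scale is its
    distance to the ``n_neighbors``-th neighbour), symmetrized by averaging
    with its transpose, then row-normalized.
    """
    n = values.shape[0]
    if n < n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors+1={n_neighbors + 1} cells, got {n}"
        )
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(values)
    dist, idx = nn.kneighbors(values)
    # dist[:, 0] is self (0); adaptive bandwidth = distance to k-th neighbour
    sigma = dist[:, -1]
    sigma = np.where(sigma <= 0, 1.0, sigma)
    W = np.zeros((n, n))
    rows = np.repeat(np.arange(n), n_neighbors + 1)
    W[rows, idx.ravel()] = np.exp(
        -(dist.ravel() ** 2) / (sigma[rows] ** 2)
    )
    W = 0.5 * (W + W.T)
    rowsum = W.sum(axis=1, keepdims=True)
    return W / rowsum


def impute(
    expr: ExpressionMatrix,
    n_neighbors: int = 15,
    t: int = 3,
    operator: np.ndarray | None = None,
) -> ExpressionMatrix:
    """Smooth expression by a t-step random walk over the affinity graph.

    ``t = 0`` returns the input unchanged.  A pre-built row-stochastic
    ``operator`` may be supplied (e.g. for testing or reuse); otherwise one
    is constructed with :func:`build_affinity`.
    """
    if t < 0:
        raise ValueError("diffusion steps t must be >= 0")
    if not np.all(np.isfinite(expr.values)):
        raise ValueError("expression matrix contains non-finite values")
    if t == 0:
        return ExpressionMatrix(
            expr.values.copy(), expr.cell_ids, list(expr.gene_ids), expr.clusters
        )
    M = build_affinity(expr.values, n_neighbors) if operator is None else operator
    if M.shape != (expr.n_cells, expr.n_cells):
        raise ValueError("affinity operator shape does not match cell count")
    out = expr.values
    for _ in range(t):
        out = M @ out
    return ExpressionMatrix(out, expr.cell_ids, list(expr.gene_ids), expr.clusters)


# ---------------------------------------------------------------------------
# On/off mixture fitting


def fit_on_off(
    x: np.ndarray,
    landmark: str = "",
    k_range: range = range(2, 9),
    n_restarts: int = 5,
    tol: float = 1e-6,
    var_floor: float = 1e-6,
    seed: int = 0,
) -> OnOffModel:
    """Fit Gaussian mixtures over ``k_range`` and reduce to on/off parameters.

    The mixture with the maximum achieved log-likelihood across k is
    selected (raw likelihood, not a penalized criterion).  The highest-mean
    component is the "on" population; the remaining components are pooled by
    moment matching: weighted mean, and variance equal to the weighted second
    moment minus the squared pooled mean.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D expression vector")
    if x.size < 20:
        raise ValueError(f"{landmark or 'landmark'}: need >= 20 cells, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{landmark or 'landmark'}: non-finite expression values")
    if np.var(x) <= 0:
        raise ValueError(
            f"landmark {landmark or '<unnamed>'} has constant (degenerate) "
            "imputed expression; cannot fit a mixture"
        )

    X = x[:, None]
    best = None
    prev_ll = -np.inf
    for k in k_range:
        gm = GaussianMixture(
            n_components=k,
            covariance_type="diag",
            n_init=n_restarts,
            tol=tol,
            reg_covar=var_floor,
            max_iter=500,
            random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm.fit(X)
        if not gm.converged_:
            logger.warning(
                "%s: EM did not converge for k=%d after %d restarts; "
                "candidate skipped", landmark or "landmark", k, n_restarts
            )
            continue
        ll = float(gm.score(X) * X.shape[0])
        if ll < prev_ll - 1e-6:
            logger.warning(
                "%s: log-likelihood decreased from k=%d to k=%d "
                "(possible EM underfit)", landmark or "landmark", k - 1, k
            )
        prev_ll = max(prev_ll, ll)
        if best is None or ll > best[0]:
            best = (ll, k, gm)

    if best is None:
        raise RuntimeError(
            f"{landmark or 'landmark'}: EM failed to converge for every k in "
            f"{list(k_range)} after {n_restarts} restarts each"
        )
    ll, k, gm = best
    means = gm.means_.ravel()
    variances = gm.covariances_.ravel()
    weights = gm.weights_.ravel()
    # On/off dichotomy: split the components at the largest gap between
    # their sorted means.  When the expressing population is captured by a
    # single component this reduces exactly to "on = highest-mean
    # component"; when raw likelihood selection over-segments a broad on
    # population, the whole upper group is pooled instead of a sliver.
    order = np.argsort(means)
    if k == 2:
        cut = 1
    else:
        gaps = np.diff(means[order])
        cut = int(np.argmax(gaps)) + 1
    on_side = order[cut:]
    off_side = order[:cut]
    mu_on, var_on = pool_components(
        means[on_side], variances[on_side], weights[on_side]
    )
    mu_off, var_off = pool_components(
        means[off_side], variances[off_side], weights[off_side]
    )
    return OnOffModel(
        landmark=landmark,
        mu_on=float(mu_on),
        var_on=float(max(var_on, var_floor)),
        mu_off=float(mu_off),
        var_off=float(max(var_off, var_floor)),
        k_selected=k,
        loglik=ll,
    )


def pool_components(
    means: np.ndarray, variances: np.ndarray, weights: np.ndarray
):
    """Moment-match a set of normal components to one (mean, variance) pair.

    Exposed separately so the pooling arithmetic can be checked in isolation.
    """
    w = np.asarray(weights, float)
    w = w / w.sum()
    mu = float(np.sum(w * means))
    var = float(np.sum(w * (np.asarray(variances) + np.asarray(means) ** 2)) - mu**2)
    return mu, var


def fit_all_landmarks(
    expr: ExpressionMatrix,
    panel: list[str],
    k_range: range = range(2, 9),
    n_restarts: int = 5,
    seed: int = 0,
) -> OnOffModelSet:
    """Fit one on/off model per retained landmark.

    Landmarks absent from the matrix or with zero reads (all-zero column)
    are excluded with a logged warning; duplicated panel entries are
    de-duplicated with a warning.  Fewer than 2 retained landmarks is an
    error.
    """
    if not panel:
        raise ValueError("landmark panel is empty")
    seen: list[str] = []
    for g in panel:
        if g in seen:
            logger.warning("panel gene %s duplicated; keeping first occurrence", g)
        else:
            seen.append(g)

    retained: list[str] = []
    models: dict[str, OnOffModel] = {}
    for g in seen:
        if g not in expr.gene_ids:
            raise KeyError(f"panel gene {g!r} absent from expression matrix")
        x = expr.gene(g)
        if np.all(x == 0):
            logger.warning(
                "landmark %s has no reads in the expression data; excluded", g
            )
            continue
        models[g] = fit_on_off(
            x, landmark=g, k_range=k_range, n_restarts=n_restarts, seed=seed
        )
        retained.append(g)

    if len(retained) < 2:
        raise ValueError(
            f"only {len(retained)} landmarks retained; need at least 2"
        )
    return OnOffModelSet(models, retained)
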