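"""Cell-to-bin probabilistic mapping.

Each unique landmark signature defines a diagonal multivariate normal over
landmark expression: for landmark l, the marginal mean/variance are the "on"
parameters where the signature bit is set and the pooled "off" parameters
where it is not.  Scoring every cell against every unique signature gives a
cells x signatures log-likelihood tensor; normalizing each signature's
column over cells with sparsegen-lin (a sparsity-controlled generalization
of sparsemax, i.e. Euclidean projection onto the probability simplex) and
broadcasting to all bins sharing the signature yields the cells x bins
mapping matrix P.  Unlike softmax, sparsemax puts exactly zero mass on
clearly incompatible cells, so each bin's distribution has sparse support.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .expression_model import ExpressionMatrix, OnOffModelSet
from .grid import SignatureGrid

__all__ = [
    "SignatureDistribution",
    "MappingMatrix",
    "signature_params",
    "log_density",
    "likelihood_tensor",
    "sparsemax",
    "sparsegen_lin",
    "build_mapping",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class SignatureDistribution:
    """Diagonal-normal parameters implied by one landmark signature."""

    signature_id: int
    mean: np.ndarray
    var: np.ndarray

    def __post_init__(self) -> None:
        if self.mean.shape != self.var.shape:
            raise ValueError("mean/var length mismatch")
        if np.any(self.var <= 0):
            raise ValueError("signature distribution has non-positive variance")


def signature_params(
    bits: np.ndarray, models: OnOffModelSet, signature_id: int = -1
) -> SignatureDistribution:
    """Assemble the per-signature mean/variance vectors from on/off models.

    Where the bit is set the landmark contributes (mu_on, var_on); where it
    is clear, the pooled (mu_off, var_off).
    """
    bits = np.asarray(bits, dtype=bool)
    if bits.shape != (len(models),):
        raise ValueError(
            f"signature length {bits.shape} does not match retained panel "
            f"size {len(models)}"
        )
    mu_on, var_on, mu_off, var_off = models.arrays()
    mean = np.where(bits, mu_on, mu_off)
    var = np.where(bits, var_on, var_off)
    return SignatureDistribution(signature_id, mean, var)


def log_density(cell_expr: np.ndarray, sd: SignatureDistribution) -> float:
    """Log diagonal multivariate normal density of one cell at one signature."""
    x = np.asarray(cell_expr, dtype=float)
    if x.shape != sd.mean.shape:
        raise ValueError("cell expression length does not match signature")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite cell expression")
    return float(
        np.sum(-0.5 * (_LOG_2PI + np.log(sd.var)) - (x - sd.mean) ** 2 / (2 * sd.var))
    )


def likelihood_tensor(
    imputed: ExpressionMatrix,
    sig_table: np.ndarray,
    models: OnOffModelSet,
) -> np.ndarray:
    """Cells x unique-signatures log-density matrix.

    ``imputed`` must be restricted to the retained landmarks in model-panel
    order.  Densities are computed once per unique signature; bins sharing a
    signature are served by broadcast downstream.
    """
    if imputed.gene_ids != models.panel:
        raise ValueError(
            "imputed matrix genes must equal the retained landmark panel, in order"
        )
    X = imputed.values  # (N, L)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite imputed expression")
    B = np.asarray(sig_table, dtype=bool)  # (S, L)
    mu_on, var_on, mu_off, var_off = models.arrays()

    # Per-landmark log-density of every cell under the on and off marginals.
    def _ld(mu, var):
        return -0.5 * (_LOG_2PI + np.log(var)) - (X - mu) ** 2 / (2 * var)

    d_on = _ld(mu_on, var_on)  # (N, L)
    d_off = _ld(mu_off, var_off)  # (N, L)
    # logdens[c, s] = sum_l [ B[s,l] ? d_on[c,l] : d_off[c,l] ]
    return d_off @ (1.0 - B.T) + d_on @ B.T.astype(float)


def sparsemax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    """Euclidean projection of ``z`` onto the probability simplex.

    Sort descending, find the support size
    ``k* = max{k : 1 + k z_(k) > sum_{j<=k} z_(j)}``, set
    ``tau = (sum_{j<=k*} z_(j) - 1) / k*`` and output ``max(z - tau, 0)``.
    Operates along ``axis`` for batched input.
    """
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise ValueError("sparsemax of an empty vector")
    if not np.all(np.isfinite(z)):
        raise ValueError("sparsemax requires finite input")
    z = np.moveaxis(z, axis, -1)
    srt = np.sort(z, axis=-1)[..., ::-1]
    csum = np.cumsum(srt, axis=-1)
    k = np.arange(1, z.shape[-1] + 1, dtype=float)
    support = 1.0 + k * srt > csum
    k_star = support.sum(axis=-1)  # >= 1 always
    idx = k_star - 1
    tau = (np.take_along_axis(csum, idx[..., None], axis=-1)[..., 0] - 1.0) / k_star
    out = np.maximum(z - tau[..., None], 0.0)
    return np.moveaxis(out, -1, axis)


def sparsegen_lin(z: np.ndarray, lam: float = 0.0, axis: int = -1) -> np.ndarray:
    """Sparsity-controlled simplex projection: ``sparsemax(z / (1 - lam))``.

    ``lam = 0`` recovers sparsemax; larger ``lam`` (< 1) yields equal or
    smaller support.
    """
    if lam >= 1:
        raise ValueError(f"sparsegen-lin requires lam < 1, got {lam}")
    return sparsemax(np.asarray(z, dtype=float) / (1.0 - lam), axis=axis)


@dataclass
class MappingMatrix:
    """Cells x bins mapping matrix P, stored per unique signature.

    ``weights[:, s]`` is the probability distribution over cells for every
    bin carrying signature ``s`` (columns of P are identical within a
    signature, so only the compact cells x signatures block is stored).
    """

    weights: np.ndarray  # (N_cells, S)
    sig_index: np.ndarray  # (bins_h, bins_w)
    cell_ids: list[str]
    grid_shape: tuple[int, int]

    def __post_init__(self) -> None:
        if self.weights.shape[0] != len(self.cell_ids):
            raise ValueError("weights rows must match cell count")
        if self.sig_index.shape != self.grid_shape:
            raise ValueError("sig_index shape must match grid shape")
        if int(self.sig_index.max()) >= self.weights.shape[1]:
            raise ValueError("sig_index references missing signature column")

    @property
    def n_cells(self) -> int:
        return self.weights.shape[0]

    @property
    def n_bins(self) -> int:
        return int(np.prod(self.grid_shape))

    def column(self, row: int, col: int) -> np.ndarray:
        """Distribution over cells for the bin at (row, col)."""
        return self.weights[:, self.sig_index[row, col]]

    def project(self, f: np.ndarray) -> np.ndarray:
        """Per-bin expectation of a per-cell feature (bins_h x bins_w)."""
        f = np.asarray(f, dtype=float)
        if f.shape != (self.n_cells,):
            raise ValueError(
                f"feature length {f.shape} does not match {self.n_cells} cells"
            )
        if not np.all(np.isfinite(f)):
            raise ValueError("non-finite feature values")
        per_sig = f @ self.weights  # (S,)
        return per_sig[self.sig_index]

    def cell_occupancy(self) -> np.ndarray:
        """Row-normalized occupancy distribution of each cell over bins.

        Returns a dense (N_cells, S) matrix of per-signature mass together
        with implicit broadcast over bins; use :meth:`to_sparse` for the
        full cells x bins matrix.
        """
        counts = np.bincount(self.sig_index.ravel(), minlength=self.weights.shape[1])
        mass = self.weights * counts[None, :]
        total = mass.sum(axis=1, keepdims=True)
        total[total == 0] = 1.0
        return mass / total

    def to_sparse(self) -> sparse.csr_matrix:
        """Materialize P as a sparse cells x bins matrix."""
        flat_sig = self.sig_index.ravel()
        cols_per_sig = [np.flatnonzero(flat_sig == s) for s in range(self.weights.shape[1])]
        rows, cols, vals = [], [], []
        for s, bins in enumerate(cols_per_sig):
            support = np.flatnonzero(self.weights[:, s])
            if support.size == 0 or bins.size == 0:
                continue
            rows.append(np.repeat(support, bins.size))
            cols.append(np.tile(bins, support.size))
            vals.append(np.repeat(self.weights[support, s], bins.size))
        if not rows:
            return sparse.csr_matrix((self.n_cells, self.n_bins))
        return sparse.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n_cells, self.n_bins),
        )


def build_mapping(
    logdens: np.ndarray,
    sig_index: np.ndarray,
    lam: float = 0.9,
    cell_ids: list[str] | None = None,
) -> MappingMatrix:
    """Normalize per-signature log-densities into the mapping matrix P.

    For each unique signature, sparsegen-lin over the cell axis turns the
    log-density column into a sparse probability distribution over cells;
    the distribution is broadcast to every bin carrying that signature.

    For numerical stability each column is shifted by its maximum *after*
    the 1/(1-lam) scaling; sparsemax is shift-invariant, so the projection
    is unchanged.
    """
    logdens = np.asarray(logdens, dtype=float)
    if logdens.ndim != 2:
        raise ValueError("logdens must be cells x signatures")
    sig_index = np.asarray(sig_index)
    if int(sig_index.max()) >= logdens.shape[1]:
        raise ValueError("sig_index references a signature not scored in logdens")
    if lam >= 1:
        raise ValueError(f"sparsegen-lin requires lam < 1, got {lam}")
    scaled = logdens / (1.0 - lam)
    scaled = scaled - scaled.max(axis=0, keepdims=True)
    weights = sparsemax(scaled, axis=0)
    if cell_ids is None:
        cell_ids = [f"cell{i}" for i in range(logdens.shape[0])]
    return MappingMatrix(
        weights=weights,
        sig_index=sig_index,
        cell_ids=cell_ids,
        grid_shape=sig_index.shape,
    )


def mapping_from_tissue(
    imputed: ExpressionMatrix,
    sg: SignatureGrid,
    models: OnOffModelSet,
    lam: float = 0.9,
) -> MappingMatrix:
    """Convenience: score + normalize in one step for a signature grid."""
    sub = imputed.subset_genes(models.panel)
    panel_idx = [sg.panel.index(g) for g in models.panel]
    sig_table = sg.sig_table[:, panel_idx]
    logdens = likelihood_tensor(sub, sig_table, models)
    return build_mapping(logdens, sg.sig_index, lam=lam, cell_ids=imputed.cell_ids)
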