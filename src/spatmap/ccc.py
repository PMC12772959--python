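"""Spatially informed ligand-receptor inference.

Complex expression obeys stoichiometry: a cell's expression of a multi-
component complex is the minimum over its component genes.  Projecting
complex expression through the mapping matrix P gives spatial abundance
distributions for ligand and receptor.  Ligand mass is then moved toward
receptor sites by *unbalanced* entropic optimal transport whose marginal
constraints are relaxed with a strength set by the ``reach`` parameter:
with KL penalty rho = reach^2 / 2, the mass transported between locations
at distance d decays like exp(-d^2 / (2 reach^2)), so ligand farther than a
few reach lengths from any receptor is simply left untransported — a soft
model of limited ligand diffusion.  Interactions are ranked by combining
component abundances with the debiased Sinkhorn divergence between the two
spatial distributions; all raw terms are reported so users can re-rank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .evaluation import SpatialDistribution, _cost_matrix, sinkhorn_divergence
from .expression_model import ExpressionMatrix
from .mapping import MappingMatrix
from .projection import SpatialField

logger = logging.getLogger(__name__)

__all__ = [
    "ComplexTable",
    "TransportResult",
    "complex_expression",
    "spatial_abundance",
    "transport_ligand",
    "rank_interactions",
]


@dataclass
class ComplexTable:
    """Curated ligand-receptor interactions (CellPhoneDB-style)."""

    interactions: list[dict]  # {"id", "ligand": [genes], "receptor": [genes]}

    def __post_init__(self) -> None:
        for it in self.interactions:
            if not it.get("ligand") or not it.get("receptor"):
                raise ValueError(
                    f"interaction {it.get('id')!r} has an empty component list"
                )

    @classmethod
    def from_cellphonedb(cls, interactions_csv, complexes_csv=None) -> "ComplexTable":
        """Load a CellPhoneDB-style interaction table.

        The interaction table needs partner columns (``partner_a``/
        ``partner_b`` or ``ligand``/``receptor``); a partner is either a
        gene symbol, an inline complex ``GENE1+GENE2``, or the name of a row
        in the complex-composition table (columns: ``complex_name`` plus
        component columns).
        """
        df = pd.read_csv(interactions_csv)
        cols = {c.lower(): c for c in df.columns}
        a = cols.get("partner_a") or cols.get("ligand")
        b = cols.get("partner_b") or cols.get("receptor")
        if a is None or b is None:
            raise ValueError(
                "interaction table needs partner_a/partner_b or ligand/receptor"
            )
        complexes: dict[str, list[str]] = {}
        if complexes_csv is not None:
            cdf = pd.read_csv(complexes_csv)
            ccols = {c.lower(): c for c in cdf.columns}
            name_col = ccols.get("complex_name")
            if name_col is None:
                raise ValueError("complex table needs a complex_name column")
            comp_cols = [
                c for c in cdf.columns
                if c.lower().startswith(("gene", "uniprot", "component"))
            ]
            for _, row in cdf.iterrows():
                comps = [
                    str(row[c]) for c in comp_cols
                    if pd.notna(row[c]) and str(row[c]).strip()
                ]
                complexes[str(row[name_col])] = comps

        def resolve(partner: str) -> list[str]:
            partner = str(partner)
            if partner in complexes:
                return complexes[partner]
            return [p.strip() for p in partner.split("+") if p.strip()]

        id_col = cols.get("id_cp_interaction") or cols.get("id")
        interactions = []
        for i, row in df.iterrows():
            iid = str(row[id_col]) if id_col else f"{row[a]}|{row[b]}"
            interactions.append(
                {"id": iid, "ligand": resolve(row[a]), "receptor": resolve(row[b])}
            )
        return cls(interactions)


@dataclass
class TransportResult:
    """Outcome of reach-limited transport of ligand mass to receptor bins."""

    receptor_points: np.ndarray  # (m, 2)
    receptor_mass: np.ndarray  # (m,)
    received: np.ndarray  # (m,) ligand mass delivered per receptor bin
    saturation: np.ndarray  # (m,) min(received / receptor_mass, 1)
    total_transported: float
    reach: float
    plan: np.ndarray | None = field(default=None, repr=False)


def _resolve_genes(expr: ExpressionMatrix, components: list[str]) -> list[str] | None:
    """Case-insensitive matching of component genes to matrix gene ids."""
    lut = {g.lower(): g for g in expr.gene_ids}
    out = []
    for c in components:
        hit = lut.get(c.lower())
        if hit is None:
            return None
        out.append(hit)
    return out


def complex_expression(expr: ExpressionMatrix, components: list[str]) -> np.ndarray:
    """Per-cell complex expression: elementwise minimum over components."""
    if not components:
        raise ValueError("empty component list")
    resolved = _resolve_genes(expr, components)
    if resolved is None:
        missing = [c for c in components if _resolve_genes(expr, [c]) is None]
        raise KeyError(f"components not in expression matrix: {missing}")
    cols = np.stack([expr.gene(g) for g in resolved], axis=1)
    return cols.min(axis=1)


def spatial_abundance(
    P: MappingMatrix,
    v: np.ndarray,
    mass_floor: float = 1e-8,
    max_support: int | None = None,
    coverage: float = 0.999,
) -> SpatialDistribution:
    """Spatial distribution of a per-cell quantity: projected expectation.

    Bins with mass below ``mass_floor`` are dropped from the support.  For
    tractable transport on large grids the support can additionally be
    truncated to the smallest set of top-mass bins covering ``coverage`` of
    the total mass, capped at ``max_support`` bins (mass outside the kept
    support is discarded, not redistributed).
    """
    v = np.asarray(v, dtype=float)
    if np.all(v == 0):
        raise ValueError("all-zero feature yields an empty spatial distribution")
    field_vals = P.project(v)
    pts = np.argwhere(field_vals > mass_floor)
    if pts.shape[0] == 0:
        raise ValueError("no bin mass above the floor")
    mass = field_vals[pts[:, 0], pts[:, 1]]
    order = np.argsort(mass)[::-1]
    total = mass.sum()
    keep = order
    if max_support is not None or coverage < 1.0:
        cum = np.cumsum(mass[order]) / total
        n_cov = int(np.searchsorted(cum, coverage) + 1)
        n_keep = min(n_cov, max_support or n_cov)
        keep = order[:n_keep]
    return SpatialDistribution(pts[keep].astype(float), mass[keep])


def transport_ligand(
    ligand: SpatialDistribution,
    receptor: SpatialDistribution,
    reach: float,
    blur: float = 2.0,
    max_iter: int = 5000,
    tol: float = 1e-8,
    keep_plan: bool = False,
) -> TransportResult:
    """Reach-limited unbalanced entropic transport of ligand to receptor.

    Both marginals are relaxed with KL penalty strength rho = reach^2 / 2;
    in the weak-regularization limit the transported mass between bins at
    distance d scales as exp(-d^2 / (2 reach^2)).  Per-receptor-bin received
    mass and saturation come from the transport plan's column sums.
    """
    if reach <= 0:
        raise ValueError(f"reach must be > 0, got {reach}")
    if blur <= 0:
        raise ValueError(f"blur must be > 0, got {blur}")
    eps = blur**2
    rho = reach**2 / 2.0
    C = _cost_matrix(ligand.points, receptor.points)
    la = np.log(np.maximum(ligand.weights, 1e-300))
    lb = np.log(np.maximum(receptor.weights, 1e-300))
    f = np.zeros(la.shape)
    g = np.zeros(lb.shape)

    def _plan(f, g, e):
        return np.exp(la[:, None] + lb[None, :] + (f[:, None] + g[None, :] - C) / e)

    # eps-annealing warm start, then iterate at the target scale until the
    # received-mass vector is stable (the plan, unlike the potentials, is
    # invariant under the slowly-equilibrating translation mode)
    eps_list = []
    e = max(float(C.max()) if C.size else eps, eps)
    while e > eps * 1.5:
        eps_list.append(e)
        e *= 0.5
    eps_list.append(eps)
    recv = None
    for e in eps_list:
        damp = rho / (rho + e)
        last = e == eps
        n_iter = max_iter if last else 5
        for it in range(n_iter):
            f = -damp * e * logsumexp(lb[None, :] + (g[None, :] - C) / e, axis=1)
            g = -damp * e * logsumexp(la[:, None] + (f[:, None] - C) / e, axis=0)
            if last and it % 5 == 4:
                recv_new = _plan(f, g, e).sum(axis=0)
                if recv is not None:
                    scale = max(float(ligand.total_mass), 1e-12)
                    if float(np.max(np.abs(recv_new - recv))) / scale < tol:
                        recv = recv_new
                        break
                recv = recv_new
        else:
            if last:
                raise RuntimeError(
                    f"unbalanced Sinkhorn did not converge within {max_iter} "
                    "iterations"
                )
    plan = _plan(f, g, eps)
    # The KL-relaxed marginals allow mass creation when receptor demand
    # exceeds local ligand supply; physically, transported ligand cannot
    # exceed what is present.  Scale rows then columns down to their
    # marginals (each pass only shrinks entries, so both caps hold after).
    rowsum = plan.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rscale = np.minimum(1.0, ligand.weights / np.where(rowsum > 0, rowsum, 1.0))
    plan *= rscale[:, None]
    colsum = plan.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cscale = np.minimum(
            1.0, receptor.weights / np.where(colsum > 0, colsum, 1.0)
        )
    plan *= cscale[None, :]
    received = plan.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        saturation = np.minimum(received / receptor.weights, 1.0)
    saturation = np.nan_to_num(saturation, nan=0.0)
    return TransportResult(
        receptor_points=receptor.points,
        receptor_mass=receptor.weights.copy(),
        received=received,
        saturation=saturation,
        total_transported=float(plan.sum()),
        reach=reach,
        plan=plan if keep_plan else None,
    )


def rank_interactions(
    db: ComplexTable,
    expr: ExpressionMatrix,
    P: MappingMatrix,
    reach: float = 10.0,
    blur: float = 2.0,
    max_support: int = 512,
    region_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Score and rank ligand-receptor interactions spatially.

    Per interaction: mean (per-cell) ligand and receptor-complex abundance,
    the debiased Sinkhorn divergence S between their spatial distributions,
    and the mean receptor saturation after reach-limited transport.  The
    composite score is ``(mean ligand abundance x mean receptor abundance)
    x exp(-S / reach^2)`` — co-localized pairs (small S) outrank distal
    pairs of equal abundance.  Interactions with components missing from the
    expression matrix are skipped with a warning; abundance-zero
    interactions score 0 and rank last.  ``region_mask`` (bins_h x bins_w
    boolean) optionally restricts scoring to a spatial region.
    """
    rows = []
    for it in db.interactions:
        lig_genes = _resolve_genes(expr, it["ligand"])
        rec_genes = _resolve_genes(expr, it["receptor"])
        if lig_genes is None or rec_genes is None:
            logger.warning(
                "interaction %s skipped: components missing from expression data",
                it["id"],
            )
            continue
        v_lig = complex_expression(expr, lig_genes)
        v_rec = complex_expression(expr, rec_genes)
        row = {
            "interaction": it["id"],
            "ligand": "+".join(lig_genes),
            "receptor": "+".join(rec_genes),
            "ligand_abundance": float(v_lig.mean()),
            "receptor_abundance": float(v_rec.mean()),
            "divergence": np.nan,
            "mean_saturation": np.nan,
            "score": 0.0,
        }
        if np.all(v_lig == 0) or np.all(v_rec == 0):
            rows.append(row)
            continue
        lig = spatial_abundance(P, v_lig, max_support=max_support)
        rec = spatial_abundance(P, v_rec, max_support=max_support)
        if region_mask is not None:
            lig = _mask_distribution(lig, region_mask)
            rec = _mask_distribution(rec, region_mask)
            if lig is None or rec is None:
                rows.append(row)
                continue
        S = sinkhorn_divergence(lig, rec, blur=blur, mode="fast")
        tr = transport_ligand(lig, rec, reach=reach, blur=blur, tol=1e-7)
        row["divergence"] = S
        row["mean_saturation"] = float(tr.saturation.mean())
        row["score"] = (
            row["ligand_abundance"]
            * row["receptor_abundance"]
            * float(np.exp(-max(S, 0.0) / reach**2))
        )
        rows.append(row)
    if not rows:
        raise ValueError("no scorable interactions")
    df = pd.DataFrame(rows).sort_values("score", ascending=False)
    return df.reset_index(drop=True)


def _mask_distribution(
    dist: SpatialDistribution, mask: np.ndarray
) -> SpatialDistribution | None:
    idx = mask[dist.points[:, 0].astype(int), dist.points[:, 1].astype(int)]
    if not idx.any():
        return None
    return SpatialDistribution(dist.points[idx], dist.weights[idx])
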