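"""Ligand-receptor inference: stoichiometry, abundance, reach-limited OT."""

import numpy as np
import pandas as pd
import pytest

from spatmap.ccc import (
    ComplexTable,
    complex_expression,
    rank_interactions,
    spatial_abundance,
    transport_ligand,
)
from spatmap.evaluation import SpatialDistribution
from spatmap.expression_model import ExpressionMatrix
from spatmap.mapping import MappingMatrix


def make_expr(values, genes):
    values = np.asarray(values, float)
    return ExpressionMatrix(
        values, [f"c{i}" for i in range(values.shape[0])], genes
    )


def tiny_P():
    weights = np.array([[1.0, 0.0], [0.0, 1.0]])
    return MappingMatrix(weights, np.array([[0, 1]]), ["c0", "c1"], (1, 2))


class TestComplexExpression:
    def test_single_component_is_identity(self):
        expr = make_expr([[1.0, 2.0], [3.0, 4.0]], ["A", "B"])
        assert np.array_equal(complex_expression(expr, ["B"]), [2.0, 4.0])

    def test_minimum_across_components(self):
        expr = make_expr([[2.0, 3.0], [5.0, 1.0]], ["A", "B"])
        assert np.array_equal(complex_expression(expr, ["A", "B"]), [2.0, 1.0])

    def test_zero_component_zeroes_cell(self):
        expr = make_expr([[0.0, 3.0]], ["A", "B"])
        assert complex_expression(expr, ["A", "B"])[0] == 0.0

    def test_case_insensitive_matching(self):
        expr = make_expr([[1.0, 2.0]], ["Tgfb1", "Tgfbr1"])
        assert complex_expression(expr, ["TGFB1"])[0] == 1.0

    def test_empty_components_rejected(self):
        with pytest.raises(ValueError):
            complex_expression(make_expr([[1.0]], ["A"]), [])

    def test_missing_component_rejected(self):
        with pytest.raises(KeyError):
            complex_expression(make_expr([[1.0]], ["A"]), ["Zzz"])


class TestSpatialAbundance:
    def test_uniform_feature_uniform_mass(self):
        d = spatial_abundance(tiny_P(), np.array([1.0, 1.0]))
        assert np.allclose(d.weights, 1.0)

    def test_linearity_in_feature(self):
        d1 = spatial_abundance(tiny_P(), np.array([1.0, 2.0]))
        d2 = spatial_abundance(tiny_P(), np.array([2.0, 4.0]))
        assert np.allclose(d2.weights, 2 * d1.weights)

    def test_mass_equals_P_row_for_indicator(self):
        d = spatial_abundance(tiny_P(), np.array([1.0, 0.0]))
        assert len(d.points) == 1
        assert tuple(d.points[0]) == (0.0, 0.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            spatial_abundance(tiny_P(), np.zeros(2))

    def test_support_truncation(self, mapping, rng):
        v = rng.random(mapping.n_cells)
        d = spatial_abundance(mapping, v, max_support=50)
        assert len(d.points) <= 50


class TestTransportLigand:
    def test_coincident_equal_masses_saturate(self, rng):
        pts = rng.uniform(0, 10, (6, 2))
        w = rng.random(6) + 0.2
        lig = SpatialDistribution(pts, w)
        rec = SpatialDistribution(pts.copy(), w.copy())
        res = transport_ligand(lig, rec, reach=1000.0, blur=1.0)
        assert np.all(res.saturation > 0.95)

    def test_distant_ligand_barely_received(self):
        lig = SpatialDistribution(np.array([[0.0, 0.0]]), np.array([1.0]))
        rec = SpatialDistribution(np.array([[0.0, 50.0]]), np.array([1.0]))
        res = transport_ligand(lig, rec, reach=5.0, blur=1.0)
        assert res.received[0] < 0.01  # 10x reach away

    def test_mass_feasibility_on_fuzzed_inputs(self):
        for seed in range(10):
            r = np.random.default_rng(seed)
            lig = SpatialDistribution(r.uniform(0, 20, (5, 2)), r.random(5) + 0.1)
            rec = SpatialDistribution(r.uniform(0, 20, (4, 2)), r.random(4) + 0.1)
            res = transport_ligand(lig, rec, reach=6.0, blur=1.5, keep_plan=True)
            assert res.total_transported <= lig.total_mass * (1 + 1e-6)
            assert np.all(res.plan.sum(axis=1) <= lig.weights * (1 + 1e-6))
            assert np.all(res.plan.sum(axis=0) <= rec.weights * (1 + 1e-6))
            assert np.all((res.saturation >= 0) & (res.saturation <= 1))

    def test_received_decays_with_distance(self):
        lig_pts = np.array([[0.0, 0.0]])
        received = []
        for d in (2.0, 6.0, 12.0, 24.0):
            rec = SpatialDistribution(np.array([[0.0, d]]), np.array([1.0]))
            res = transport_ligand(
                SpatialDistribution(lig_pts, np.array([1.0])), rec,
                reach=4.0, blur=1.0,
            )
            received.append(res.received[0])
        assert received == sorted(received, reverse=True)

    def test_invalid_reach_rejected(self):
        d = SpatialDistribution(np.zeros((1, 2)), np.array([1.0]))
        with pytest.raises(ValueError):
            transport_ligand(d, d, reach=0.0)


class TestComplexTable:
    def test_inline_complex_parsing(self, tmp_path):
        p = tmp_path / "inter.csv"
        p.write_text("partner_a,partner_b\nDll1,Notch1+Notch2\n")
        db = ComplexTable.from_cellphonedb(p)
        assert db.interactions[0]["ligand"] == ["Dll1"]
        assert db.interactions[0]["receptor"] == ["Notch1", "Notch2"]

    def test_complex_table_resolution(self, tmp_path):
        inter = tmp_path / "inter.csv"
        inter.write_text("id_cp_interaction,partner_a,partner_b\nI1,Tgfb1,TGFR_complex\n")
        comp = tmp_path / "complex.csv"
        comp.write_text("complex_name,gene_1,gene_2\nTGFR_complex,Tgfbr1,Tgfbr2\n")
        db = ComplexTable.from_cellphonedb(inter, comp)
        assert db.interactions[0]["receptor"] == ["Tgfbr1", "Tgfbr2"]

    def test_empty_component_list_rejected(self):
        with pytest.raises(ValueError):
            ComplexTable([{"id": "x", "ligand": [], "receptor": ["A"]}])


def _signaling_db():
    return ComplexTable(
        [
            {"id": "true", "ligand": ["LigTrue"], "receptor": ["Rec1", "Rec2"]},
            {"id": "decoy", "ligand": ["LigDecoy"], "receptor": ["Rec1", "Rec2"]},
            {"id": "ghost", "ligand": ["NotAGene"], "receptor": ["Rec1"]},
        ]
    )


@pytest.fixture(scope="module")
def ranked():
    import spatmap as sm
    from spatmap.mapping import mapping_from_tissue

    spec = sm.communication_spec(seed=0, n_cells=700)
    tissue = sm.simulate_tissue(spec)
    sg = sm.aggregate_reads(
        tissue.reads,
        sm.GridSpec(spec.width_px, spec.height_px, spec.tile),
        list(spec.landmarks),
    )
    imp = sm.impute(tissue.expr)
    models = sm.fit_all_landmarks(
        imp, list(spec.landmarks), k_range=range(2, 5), n_restarts=2, seed=0
    )
    P = mapping_from_tissue(imp, sg, models, lam=0.9)
    return rank_interactions(_signaling_db(), tissue.expr, P, reach=30.0, blur=2.0)


class TestRankInteractions:
    def test_colocalized_pair_outranks_decoy(self, ranked):
        order = list(ranked["interaction"])
        assert order.index("true") < order.index("decoy")

    def test_missing_component_skipped(self, ranked):
        assert "ghost" not in set(ranked["interaction"])

    def test_divergence_smaller_for_colocalized(self, ranked):
        r = ranked.set_index("interaction")
        assert r.loc["true", "divergence"] < r.loc["decoy", "divergence"]

    def test_zero_abundance_ranks_last(self):
        expr = make_expr([[1.0, 0.0, 1.0], [2.0, 0.0, 1.0]], ["A", "B", "C"])
        db = ComplexTable(
            [
                {"id": "live", "ligand": ["A"], "receptor": ["C"]},
                {"id": "dead", "ligand": ["B"], "receptor": ["C"]},
            ]
        )
        ranked = rank_interactions(db, expr, tiny_P(), reach=5.0)
        assert list(ranked["interaction"]) == ["live", "dead"]
        assert ranked.set_index("interaction").loc["dead", "score"] == 0.0
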