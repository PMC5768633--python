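"""Pearson edge candidates, threshold filtering, cis/trans labels, network export."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from lxml import etree

from lhnet import coexnet, exprio, synthdata
from lhnet.exprio import ExpressionMatrix


def _gene_matrix(rows: dict[str, list[float]]) -> ExpressionMatrix:
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = [f"s{j}" for j in range(df.shape[1])]
    return ExpressionMatrix(df, level="gene")


def _pearson_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return (xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum())


def _p_from_r(r, n):
    from scipy import stats

    t = abs(r) * math.sqrt((n - 2) / (1 - r * r))
    return 2 * stats.t.sf(t, n - 2)


class TestCorrelatePairs:
    def test_perfect_linearity(self):
        gm = _gene_matrix({"lnc1": [1, 2, 3, 4], "m1": [2, 4, 6, 8]})
        cand = coexnet.correlate_pairs(gm, {"lnc1"}, {"m1"})
        assert cand.loc[0, "r"] == pytest.approx(1.0)
        assert cand.loc[0, "p"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_covariance_oracle(self):
        x, y = [1, 2, 3, 4], [1, 2, 3, 5]
        gm = _gene_matrix({"lnc1": x, "m1": y})
        cand = coexnet.correlate_pairs(gm, {"lnc1"}, {"m1"})
        assert cand.loc[0, "r"] == pytest.approx(0.9827, abs=5e-5)
        assert cand.loc[0, "r_squared"] == pytest.approx(0.9657, abs=5e-5)
        assert cand.loc[0, "r"] == pytest.approx(_pearson_oracle(x, y))

    def test_constant_gene_skipped_with_warning(self, caplog):
        gm = _gene_matrix({"lnc1": [1, 2, 3, 4], "m1": [5, 5, 5, 5]})
        with caplog.at_level("WARNING"):
            cand = coexnet.correlate_pairs(gm, {"lnc1"}, {"m1"})
        assert cand.empty
        assert any("zero variance" in r.message for r in caplog.records)

    def test_overlapping_sets_rejected(self):
        gm = _gene_matrix({"g1": [1, 2, 3], "g2": [3, 2, 1]})
        with pytest.raises(ValueError, match="overlap"):
            coexnet.correlate_pairs(gm, {"g1"}, {"g1", "g2"})

    def test_too_few_samples_rejected(self):
        gm = _gene_matrix({"g1": [1, 2], "g2": [3, 2]})
        with pytest.raises(ValueError, match="3 samples"):
            coexnet.correlate_pairs(gm, {"g1"}, {"g2"})


class TestFilterEdges:
    def _cand(self, r, n=8):
        return pd.DataFrame(
            {"lnc_gene": ["l"], "mrna_gene": ["m"], "r": [r], "r_squared": [r * r],
             "p": [_p_from_r(r, n)]}
        )

    def test_strong_negative_correlation_retained(self):
        edges = coexnet.filter_edges(self._cand(-0.96, n=8))
        assert len(edges) == 1
        assert edges.loc[0, "sign"] == "negative"
        assert edges.loc[0, "p"] < 0.01  # ~1.6e-4 via the t transform

    def test_r_squared_below_threshold_rejected(self):
        cand = self._cand(math.sqrt(0.89), n=30)
        assert cand.loc[0, "p"] < 1e-6  # significant but weak
        assert coexnet.filter_edges(cand).empty

    def test_inclusive_boundary_retained(self):
        r = math.sqrt(0.9)
        cand = pd.DataFrame(
            {"lnc_gene": ["l"], "mrna_gene": ["m"], "r": [r], "r_squared": [0.9], "p": [1e-5]}
        )
        assert len(coexnet.filter_edges(cand)) == 1

    def test_r2_filter_alone_equivalent_at_n8(self):
        # with 8 samples, |r| >= sqrt(0.9) already implies p < 0.01
        rng = np.random.default_rng(0)
        gm = ExpressionMatrix(
            pd.DataFrame(
                rng.lognormal(1, 1, (60, 8)),
                index=[f"g{i}" for i in range(60)],
                columns=[f"s{j}" for j in range(8)],
            ),
            level="gene",
        )
        cand = coexnet.correlate_pairs(gm, {f"g{i}" for i in range(30)},
                                       {f"g{i}" for i in range(30, 60)})
        both = coexnet.filter_edges(cand, r2_min=0.9, p_max=0.01)
        r2_only = coexnet.filter_edges(cand, r2_min=0.9, p_max=1.0)
        pd.testing.assert_frame_equal(both, r2_only)


class TestCisTrans:
    def _spans(self, rows):
        df = pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end"])
        return df.set_index("gene_id")

    def _edge(self, lnc="l", mrna="m"):
        return pd.DataFrame(
            {"lnc_gene": [lnc], "mrna_gene": [mrna], "r": [0.99], "r_squared": [0.98],
             "p": [1e-6], "sign": ["positive"]}
        )

    def test_boundary_gap_arithmetic(self):
        spans = self._spans([("l", "chr1", 1_000_000, 1_005_000),
                             ("m", "chr1", 1_900_000, 1_950_000)])
        out = coexnet.classify_cis_trans(self._edge(), spans)
        assert out.loc[0, "distance_bp"] == 895_000
        assert out.loc[0, "locality"] == "cis"

    def test_different_chromosomes_trans(self):
        spans = self._spans([("l", "chr1", 100, 200), ("m", "chr2", 100, 200)])
        out = coexnet.classify_cis_trans(self._edge(), spans)
        assert out.loc[0, "locality"] == "trans"
        assert np.isnan(out.loc[0, "distance_bp"])

    def test_window_boundary_inclusive(self):
        spans = self._spans([("l", "chr1", 1, 100), ("m", "chr1", 1_000_100, 1_000_200)])
        out = coexnet.classify_cis_trans(self._edge(), spans)
        assert out.loc[0, "distance_bp"] == 1_000_000
        assert out.loc[0, "locality"] == "cis"

    def test_overlapping_spans_distance_zero(self):
        spans = self._spans([("l", "chr1", 100, 500), ("m", "chr1", 300, 900)])
        out = coexnet.classify_cis_trans(self._edge(), spans)
        assert out.loc[0, "distance_bp"] == 0

    def test_missing_annotation_rejected(self):
        spans = self._spans([("l", "chr1", 1, 2)])
        with pytest.raises(ValueError, match="missing"):
            coexnet.classify_cis_trans(self._edge(), spans)


class TestBuildNetwork:
    def _edges(self, pairs):
        return pd.DataFrame(
            [
                {"lnc_gene": a, "mrna_gene": b, "r": 0.99, "r_squared": 0.98,
                 "p": 1e-6, "sign": "positive", "locality": "trans", "distance_bp": np.nan}
                for a, b in pairs
            ]
        )

    def test_empty_network(self):
        g = coexnet.build_network(pd.DataFrame(columns=coexnet.EDGE_COLUMNS))
        stats = coexnet.network_stats(g)
        assert stats["n_edges"] == 0 and stats["frac_lnc_connected"] == 0.0

    def test_duplicate_edges_collapse(self):
        g = coexnet.build_network(self._edges([("l1", "m1"), ("l1", "m1")]))
        assert g.number_of_edges() == 1

    def test_role_collision_rejected(self):
        with pytest.raises(ValueError, match="both"):
            coexnet.build_network(self._edges([("l1", "m1"), ("m1", "x")]))

    def test_bipartite_for_random_inputs(self):
        rng = np.random.default_rng(0)
        pairs = {(f"l{rng.integers(5)}", f"m{rng.integers(5)}") for _ in range(20)}
        g = coexnet.build_network(self._edges(sorted(pairs)))
        for u, v in g.edges():
            assert {g.nodes[u]["role"], g.nodes[v]["role"]} == {"lncRNA", "mRNA"}
        assert g.number_of_edges() == len(pairs)

    def test_planted_pair_recovery(self):
        """Per-pair recovery probability at rho=0.98, n=8 is ~0.91; over 100
        planted pairs the full gene-level path should recover >= 85."""
        cfg = synthdata.SimulationConfig(
            seed=8, n_transcripts=600, n_pairs=100, n_de_lh=0, n_de_handling=0,
            n_de_resilience=0, pairs_are_de=False,
        )
        matrix, annotation, truth = synthdata.simulate_expression(cfg)
        gm = exprio.gene_level_average(matrix, annotation)
        design = synthdata.default_design()
        samples = [s for s in gm.sample_ids if design[s] in ("LH", "Ctrl")]
        pair_truth = truth[truth["de_class"] == "pair"]
        spans = exprio.gene_spans(annotation)
        lnc = {g for g in pair_truth["gene_id"] if spans.loc[g, "biotype"] != "protein_coding"}
        mrna = {g for g in pair_truth["gene_id"] if spans.loc[g, "biotype"] == "protein_coding"}
        # add null lncRNAs as decoys
        null_lnc = {
            g for g in truth.loc[truth["de_class"] == "null", "gene_id"].unique()
            if spans.loc[g, "biotype"] in exprio.LNCRNA_BIOTYPES
        }
        cand = coexnet.correlate_pairs(gm, lnc | null_lnc, mrna, samples)
        edges = coexnet.filter_edges(cand)
        recovered = set(zip(edges["lnc_gene"], edges["mrna_gene"]))
        planted = {
            (row.gene_id, row.partner_gene)
            for row in pair_truth.itertuples()
            if row.gene_id in lnc
        }
        assert len(planted) == 100
        assert len(planted & recovered) >= 85

    def test_sensitivity_monotone_in_population_r(self):
        rates = []
        for rho in (0.8, 0.95, 0.995):
            cfg = synthdata.SimulationConfig(
                seed=9, n_transcripts=800, n_pairs=400, n_de_lh=0, n_de_handling=0,
                n_de_resilience=0, pairs_are_de=False, pair_r=rho,
            )
            matrix, annotation, truth = synthdata.simulate_expression(cfg)
            design = synthdata.default_design()
            samples = design.index[design.isin(["LH", "Ctrl"])].tolist()
            vals = matrix.data[samples].to_numpy()
            x = vals[:400]
            y = vals[400:800]
            xc = x - x.mean(1, keepdims=True)
            yc = y - y.mean(1, keepdims=True)
            r = (xc * yc).sum(1) / np.sqrt((xc**2).sum(1) * (yc**2).sum(1))
            rates.append((r**2 >= 0.9).mean())
        assert rates[0] < rates[1] < rates[2]


class TestExport:
    def _network(self):
        edges = pd.DataFrame(
            [
                {"lnc_gene": "l1", "mrna_gene": "m1", "r": 0.99, "r_squared": 0.9801,
                 "p": 1e-6, "sign": "positive", "locality": "cis", "distance_bp": 5000.0},
                {"lnc_gene": "l1", "mrna_gene": "m2", "r": -0.97, "r_squared": 0.9409,
                 "p": 1e-4, "sign": "negative", "locality": "trans", "distance_bp": np.nan},
            ]
        )
        return coexnet.build_network(edges, comparison="LHvsCtrl")

    def test_sif_one_line_per_edge(self, tmp_path):
        g = self._network()
        written = coexnet.export_network(g, tmp_path, formats=("sif",))
        lines = written["sif"].read_text().strip().splitlines()
        assert len(lines) == 2
        assert lines[0].split("\t") == ["l1", "coexp", "m1"]

    def test_tsv_round_trip(self, tmp_path):
        g = self._network()
        written = coexnet.export_network(g, tmp_path, formats=("tsv",))
        back = coexnet.import_network_tsv(written["nodes_tsv"], written["edges_tsv"])
        assert set(back.nodes) == set(g.nodes)
        assert set(map(frozenset, back.edges)) == set(map(frozenset, g.edges))
        for u, v, d in g.edges(data=True):
            assert back.edges[u, v]["r"] == pytest.approx(d["r"])
            assert back.edges[u, v]["locality"] == d["locality"]

    def test_graphml_is_valid_xml_with_graphml_root(self, tmp_path):
        written = coexnet.export_network(self._network(), tmp_path, formats=("graphml",))
        tree = etree.parse(str(written["graphml"]))
        root = tree.getroot()
        assert root.tag == "{http://graphml.graphdrawing.org/xmlns}graphml"
        reread = nx.read_graphml(written["graphml"])
        assert reread.number_of_edges() == 2

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="format"):
            coexnet.export_network(self._network(), tmp_path, formats=("dot",))
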