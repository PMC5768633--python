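"""Generator contracts: determinism, planted-truth consistency, degenerate cases."""

import numpy as np
import pandas as pd
import pytest

from lhnet import behavior, enrich, exprio, qpcr, synthdata
from lhnet.synthdata import SimulationConfig


class TestSimulateBehavior:
    def test_determinism_under_fixed_seed(self):
        t1, truth1 = synthdata.simulate_behavior(seed=7)
        t2, truth2 = synthdata.simulate_behavior(seed=7)
        assert t1.to_csv() == t2.to_csv()
        assert truth1.to_csv() == truth2.to_csv()

    def test_zero_noise_degenerate_clusters(self):
        table, truth = synthdata.simulate_behavior(
            cluster_means=((25, 8), (5, 3)), cluster_sds=((0, 0), (0, 0)), seed=0
        )
        lh = table[table["group"] == "LH"]
        nlh = table[table["group"] == "NLH"]
        assert (lh["failures"] == 25).all() and (lh["latency_s"] == 8).all()
        assert (nlh["failures"] == 5).all() and (nlh["latency_s"] == 3).all()

    def test_bounds_and_uniqueness(self):
        table, _ = synthdata.simulate_behavior(
            cluster_means=((40, 20), (-5, -2)), cluster_sds=((5, 3), (5, 3)), seed=1
        )
        assert table["failures"].between(0, 30).all()
        assert table["latency_s"].between(0, 10).all()
        assert table["mouse_id"].is_unique

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            synthdata.simulate_behavior(cluster_sds=((-1, 1), (1, 1)))

    def test_kmeans_recovers_truth_over_seeds(self):
        """Downstream clustering recovers planted labels on >=95% of seeds."""
        perfect = 0
        for seed in range(100):
            table, truth = synthdata.simulate_behavior(seed=seed)
            stressed = table[table["group"] != "Ctrl"]
            res = behavior.cluster_mice(stressed, seed=seed)
            agree = (
                res.labels.reindex(truth["mouse_id"]).values == truth["true_class"].values
            ).all()
            perfect += bool(agree)
        assert perfect >= 95


class TestSimulateExpression:
    def test_seed_contract(self):
        cfg = SimulationConfig(seed=5, n_transcripts=300)
        m1, a1, t1 = synthdata.simulate_expression(cfg)
        m2, a2, t2 = synthdata.simulate_expression(cfg)
        pd.testing.assert_frame_equal(m1.data, m2.data)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(t1, t2)
        m3, *_ = synthdata.simulate_expression(SimulationConfig(seed=6, n_transcripts=300))
        assert not m1.data.equals(m3.data)

    def test_zero_noise_pair_is_perfectly_correlated(self):
        cfg = SimulationConfig(seed=0, n_transcripts=50, n_pairs=3, n_de_lh=0,
                               n_de_handling=0, n_de_resilience=0, noise_sd=0.0)
        matrix, _, truth = synthdata.simulate_expression(cfg)
        vals = matrix.data.to_numpy()
        for i in range(3):
            x, y = vals[i], vals[3 + i]
            r = np.corrcoef(x, y)[0, 1]
            assert r == pytest.approx(1.0, abs=1e-12)

    def test_mean_sample_r2_matches_monte_carlo_oracle(self):
        """Generator pairs reproduce the bivariate-normal r^2 distribution."""
        cfg = SimulationConfig(seed=2, n_transcripts=2000, n_pairs=1000, n_de_lh=0,
                               n_de_handling=0, n_de_resilience=0, pairs_are_de=False)
        matrix, _, _ = synthdata.simulate_expression(cfg)
        design = synthdata.default_design()
        samples = design.index[design.isin(["LH", "Ctrl"])].tolist()
        vals = matrix.data[samples].to_numpy()
        x, y = vals[:1000], vals[1000:2000]
        xc = x - x.mean(1, keepdims=True)
        yc = y - y.mean(1, keepdims=True)
        r = (xc * yc).sum(1) / np.sqrt((xc**2).sum(1) * (yc**2).sum(1))
        # independent oracle: brute-force Monte-Carlo at the same rho and n
        rng = np.random.default_rng(12345)
        reps, n, rho = 20000, len(samples), cfg.pair_r
        z1 = rng.standard_normal((reps, n))
        z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal((reps, n))
        z1c = z1 - z1.mean(1, keepdims=True)
        z2c = z2 - z2.mean(1, keepdims=True)
        r_mc = (z1c * z2c).sum(1) / np.sqrt((z1c**2).sum(1) * (z2c**2).sum(1))
        assert np.mean(r**2) == pytest.approx(np.mean(r_mc**2), abs=0.03)

    def test_truth_is_symmetric_and_complete(self, study):
        _, annotation, truth = study
        pairs = truth[truth["de_class"] == "pair"]
        partner = pairs.set_index("gene_id")["partner_gene"]
        for gene, mate in partner.items():
            assert partner[mate] == gene
        assert pairs["pair_locality"].isin(["cis", "trans"]).all()
        assert set(pairs["pair_locality"]) == {"cis", "trans"}
        de = truth[truth["de_class"] == "lh"]
        assert (de["de_LHvsCtrl"] != "null").all()
        assert (de["de_LHvsNLH"] != "null").all()
        assert (de["de_CtrlvsHC"] == "null").all()

    def test_handling_class_only_de_vs_homecage(self, study):
        *_, truth = study
        handling = truth[truth["de_class"] == "handling"]
        assert (handling["de_CtrlvsHC"] != "null").all()
        assert (handling["de_LHvsCtrl"] == "null").all()
        assert (handling["de_LHvsNLH"] == "null").all()

    def test_planted_cis_pairs_within_window(self, study):
        _, annotation, truth = study
        spans = exprio.gene_spans(annotation)
        cis = truth[(truth["de_class"] == "pair") & (truth["pair_locality"] == "cis")]
        for row in cis.itertuples():
            a, b = spans.loc[row.gene_id], spans.loc[row.partner_gene]
            assert a["chromosome"] == b["chromosome"]
            gap = max(0, max(a["start"], b["start"]) - min(a["end"], b["end"]))
            assert gap <= 1_000_000

    def test_values_nonnegative_annotation_valid(self, study):
        matrix, annotation, _ = study
        assert (matrix.data.to_numpy() >= 0).all()
        assert (annotation["start"] <= annotation["end"]).all()
        assert annotation["biotype"].isin(exprio.BIOTYPES).all()
        lnc_frac = (
            annotation["biotype"].isin(exprio.LNCRNA_BIOTYPES).mean()
        )
        assert 0.05 < lnc_frac < 0.4

    def test_too_many_planted_features_rejected(self):
        with pytest.raises(ValueError, match="planted"):
            synthdata.simulate_expression(SimulationConfig(n_transcripts=100))


class TestSimulateQpcr:
    def test_zero_noise_inverts_exactly(self):
        plate = synthdata.simulate_qpcr({"A": 2.0, "B": 1.0}, n_per_group=3, ct_noise_sd=0.0)
        rel = qpcr.ddct(plate)
        lh = rel[rel["group"] == "LH"].set_index("gene")
        assert lh.loc["A", "percent_of_control"].mean() == pytest.approx(200.0, rel=1e-9)
        assert lh.loc["B", "percent_of_control"].mean() == pytest.approx(100.0, rel=1e-9)

    def test_noisy_half_fold_recovered_within_error(self):
        plate = synthdata.simulate_qpcr({"A": 0.5}, n_per_group=10, ct_noise_sd=0.1, seed=4)
        rel = qpcr.ddct(plate)
        mean_pct = rel.loc[rel["group"] == "LH", "percent_of_control"].mean()
        # Ct noise of 0.1 cycles -> ~7% relative sd per sample; 3 sigma of the mean
        assert mean_pct == pytest.approx(50.0, abs=3 * 0.07 * 50 / np.sqrt(10) + 1.5)

    def test_nonpositive_fold_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            synthdata.simulate_qpcr({"A": 0.0})


class TestSimulateGeneSets:
    def test_determinism(self, study):
        _, annotation, truth = study
        c1, e1 = synthdata.simulate_gene_sets(annotation, truth, seed=3)
        c2, e2 = synthdata.simulate_gene_sets(annotation, truth, seed=3)
        assert c1 == c2 and e1 == e2

    def test_enriched_terms_detected_by_fisher(self, study):
        _, annotation, truth = study
        collection, enriched = synthdata.simulate_gene_sets(annotation, truth, seed=0)
        background = set(annotation["gene_id"].unique())
        query = set(
            truth.loc[
                (truth["de_LHvsCtrl"] != "null")
                & truth["gene_id"].isin(
                    annotation.loc[annotation["biotype"] == "protein_coding", "gene_id"]
                ),
                "gene_id",
            ]
        )
        res = enrich.fisher_enrichment(query, background, collection).set_index("term_id")
        assert (res.loc[enriched, "p"] < 0.05).all()

    def test_universe_term_not_enriched(self):
        background = {f"g{i}" for i in range(50)}
        coll = {"ALL": ("everything", frozenset(background))}
        res = enrich.fisher_enrichment({f"g{i}" for i in range(10)}, background, coll)
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_more_enriched_than_total_rejected(self, study):
        _, annotation, truth = study
        with pytest.raises(ValueError, match="enriched"):
            synthdata.simulate_gene_sets(annotation, truth, n_terms=2, enriched_terms=3)


class TestGenerateStudy:
    def test_all_files_written_and_readable(self, study_files):
        paths = study_files
        matrix = exprio.read_expression(paths["expression"])
        ann = exprio.read_annotation(paths["annotation_tsv"])
        design = exprio.read_metadata(paths["metadata"])
        assert set(design.values) == set(exprio.GROUPS)
        assert matrix.data.shape[1] == len(design)
        assert set(matrix.feature_ids) == set(ann["transcript_id"])
        collection = enrich.read_gmt(paths["gene_sets"])
        assert collection
        plate = qpcr.read_qpcr(paths["qpcr"])
        assert {"GAPDH"} <= set(plate["gene"])

    def test_gtf_and_tsv_annotations_agree(self, study_files):
        from_tsv = exprio.read_annotation(study_files["annotation_tsv"], format="tsv")
        from_gtf = exprio.read_annotation(study_files["annotation_gtf"], format="gtf")
        pd.testing.assert_frame_equal(
            from_tsv.sort_values("transcript_id").reset_index(drop=True),
            from_gtf.sort_values("transcript_id").reset_index(drop=True),
        )
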