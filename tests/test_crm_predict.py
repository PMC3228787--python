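import numpy as np
import pytest

from crmkit.crm_predict import (
    CRMWindow,
    GeneAnnotation,
    LRAModel,
    SearchRegionSpec,
    build_search_regions,
    cluster_score,
    conservation_filter,
    predict_crms,
    train_lra,
    window_features,
)
from crmkit.io_formats import ScoreTrack
from crmkit.motif_scan import SiteHit, pfm_to_pwm, scan
from crmkit.synthetic_data import SimConfig, gen_conservation_track, gen_genome, muscle_motifs
from crmkit.enrichment_stats import roc_auc


def _hit(offset, motif="M1", rel=0.9, length=6, strand="+"):
    return SiteHit("r", offset, length, strand, motif, rel * 10, rel)


class TestBuildSearchRegions:
    def test_plain_tss_flank(self):
        ann = GeneAnnotation("chr1", tss=[50_000])
        (r,) = build_search_regions(ann)
        assert (r.start, r.end) == (40_000, 60_000)

    def test_coding_exon_removed(self):
        ann = GeneAnnotation("chr1", tss=[50_000], coding_exons=[(49_000, 49_500)])
        regions = build_search_regions(ann)
        assert [(r.start, r.end) for r in regions] == [(40_000, 49_000), (49_500, 60_000)]

    def test_alt_tss_exclusion_zone(self):
        ann = GeneAnnotation("chr1", tss=[50_000], alt_tss=[55_000])
        regions = build_search_regions(ann)
        assert [(r.start, r.end) for r in regions] == [(40_000, 54_950), (55_050, 60_000)]

    def test_clip_to_chromosome(self):
        ann = GeneAnnotation("chr1", tss=[4_000], chrom_length=9_000)
        (r,) = build_search_regions(ann)
        assert (r.start, r.end) == (0, 9_000)

    def test_overlapping_tss_windows_merge(self):
        ann = GeneAnnotation("chr1", tss=[50_000, 55_000])
        (r,) = build_search_regions(ann)
        assert (r.start, r.end) == (40_000, 65_000)

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            SearchRegionSpec(tss_flank=10, alt_tss_exclusion=10)


class TestWindowFeatures:
    def test_empty_hits_all_zero(self):
        ws = window_features([], 400, motif_ids=["M1"], window=200, step=50)
        assert all(w.best_rel["M1"] == 0.0 and w.n_hits["M1"] == 0 for w in ws)

    def test_hit_counted_in_every_intersecting_window(self):
        ws = window_features([_hit(198)], 400, motif_ids=["M1"], window=200, step=50)
        containing = [w for w in ws if w.n_hits["M1"] == 1]
        # windows starting at 0, 50, 100, 150, 200 all intersect [198, 204)
        assert [(w.start) for w in containing] == [0, 50, 100, 150, 200]

    def test_features_match_brute_force_recount(self, rng):
        hits = [
            _hit(int(rng.integers(0, 990)), motif=str(rng.choice(["A", "B"])),
                 rel=float(rng.uniform(0.8, 1.0)))
            for _ in range(60)
        ]
        ws = window_features(hits, 1000, motif_ids=["A", "B"], window=200, step=50)
        for w in ws:
            for m in ("A", "B"):
                inter = [h for h in hits if h.motif_id == m and h.offset < w.end and h.end > w.start]
                assert w.n_hits[m] == len(inter)
                assert np.isclose(w.best_rel[m], max((h.rel_score for h in inter), default=0.0))

    def test_windows_tile_region(self):
        ws = window_features([], 430, motif_ids=["M1"], window=200, step=50)
        assert ws[0].start == 0 and ws[-1].end == 430


def _window(best, count, motif_ids=("M1", "M2")):
    return CRMWindow("r", 0, 200, dict(zip(motif_ids, best)), dict(zip(motif_ids, count)))


class TestTrainLra:
    def test_identical_classes_near_zero_weights(self, rng):
        ws = [
            _window([float(rng.random()), float(rng.random())], [1, 1])
            for _ in range(100)
        ]
        model = train_lra(ws, ws, ["M1", "M2"], seed=0)
        assert np.all(np.abs(model.weights) < 0.5)
        scores = [model.score(w) for w in ws]
        assert abs(np.mean(scores) - 0.5) < 0.1

    def test_separable_classes_train_auc_one(self, rng):
        pos = [_window([0.9, 0.9], [3, 3]) for _ in range(50)]
        neg = [_window([0.0, 0.0], [0, 0]) for _ in range(50)]
        model = train_lra(pos, neg, ["M1", "M2"], seed=0)
        scores = np.array([model.score(w) for w in pos + neg])
        labels = np.array([1] * 50 + [0] * 50)
        assert roc_auc(scores, labels).auc == 1.0

    def test_sign_recovery_from_known_model(self, rng):
        # simulate window features and labels from a known logistic model
        true_w = np.array([2.5, -1.5, 1.2, -0.8])
        X = rng.random((2000, 4))
        p = 1 / (1 + np.exp(-(X @ true_w - 0.5)))
        y = rng.random(2000) < p
        # two motifs -> 4 features (best M1, best M2, n M1, n M2)
        windows = [
            CRMWindow("r", 0, 200, {"M1": x[0], "M2": x[1]},
                      {"M1": x[2], "M2": x[3]}, [])
            for x in X
        ]
        model = train_lra(
            [w for w, yy in zip(windows, y) if yy],
            [w for w, yy in zip(windows, y) if not yy],
            ["M1", "M2"],
            seed=0,
        )
        assert np.all(np.sign(model.weights) == np.sign(true_w))

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            train_lra([], [_window([0.1, 0.1], [0, 0])], ["M1", "M2"])

    def test_deterministic_and_round_trips(self, tmp_path, rng):
        pos = [_window([float(rng.random()), 0.9], [2, 1]) for _ in range(30)]
        neg = [_window([float(rng.random()) * 0.3, 0.1], [0, 0]) for _ in range(30)]
        m1 = train_lra(pos, neg, ["M1", "M2"], seed=3)
        m2 = train_lra(pos, neg, ["M1", "M2"], seed=3)
        np.testing.assert_array_equal(m1.weights, m2.weights)
        m1.save(tmp_path / "m.json")
        back = LRAModel.load(tmp_path / "m.json")
        np.testing.assert_allclose(back.weights, m1.weights)


class TestClusterScore:
    def test_no_hits_zero(self):
        assert cluster_score(CRMWindow("r", 0, 200, {}, {}, [])) == 0.0

    def test_two_disjoint_full_hits(self):
        w = CRMWindow("r", 0, 200, {}, {}, [_hit(0, rel=1.0), _hit(10, rel=1.0)])
        assert np.isclose(cluster_score(w, gap_penalty=0.0), 2.0)

    def test_monotone_in_hits_at_zero_gap_penalty(self, rng):
        hits = []
        prev = 0.0
        for k in range(12):
            hits.append(_hit(int(rng.integers(0, 194)), rel=float(rng.uniform(0.8, 1))))
            w = CRMWindow("r", 0, 200, {}, {}, list(hits))
            score = cluster_score(w, gap_penalty=0.0)
            assert score >= prev - 1e-12
            prev = score

    def test_gap_penalty_subtracts_uncovered_fraction(self):
        w = CRMWindow("r", 0, 200, {}, {}, [_hit(0, rel=1.0)])
        # 6 of 200 bp covered
        expect = 1.0 - 1.0 * (1 - 6 / 200)
        assert np.isclose(cluster_score(w, gap_penalty=1.0), expect)


class TestPredictCrms:
    def _model(self):
        # hand-built model: positive weight on best rel scores
        return LRAModel(["SP1", "MEF2A"], np.array([4.0, 4.0, 0.0, 0.0]), -3.0)

    def test_sp1_only_prediction_excluded(self):
        w = CRMWindow("r", 0, 200, {"SP1": 1.0, "MEF2A": 0.0}, {"SP1": 2, "MEF2A": 0},
                      [_hit(5, motif="SP1")])
        assert predict_crms([w], self._model(), 0.5) == []

    def test_sp1_plus_mef2a_retained(self):
        w = CRMWindow("r", 0, 200, {"SP1": 1.0, "MEF2A": 1.0}, {"SP1": 1, "MEF2A": 1},
                      [_hit(5, motif="SP1"), _hit(20, motif="MEF2A")])
        preds = predict_crms([w], self._model(), 0.5)
        assert len(preds) == 1 and preds[0].motif_ids == {"SP1", "MEF2A"}

    def test_adjacent_windows_merge_and_merge_is_idempotent(self):
        hits1 = [_hit(10, motif="MEF2A")]
        hits2 = [_hit(210, motif="MEF2A")]
        w1 = CRMWindow("r", 0, 200, {"SP1": 0, "MEF2A": 1.0}, {"SP1": 0, "MEF2A": 1}, hits1)
        w2 = CRMWindow("r", 150, 350, {"SP1": 0, "MEF2A": 1.0}, {"SP1": 0, "MEF2A": 1}, hits2)
        preds = predict_crms([w1, w2], self._model(), 0.5)
        assert len(preds) == 1
        assert (preds[0].start, preds[0].end) == (0, 350)
        assert len(preds[0].hits) == 2

    def test_planted_crm_recovery_auc(self):
        cfg = SimConfig(seed=5, genome_length=30_000, n_crm=10)
        pfms = muscle_motifs()
        genome, truth = gen_genome(cfg, pfms)
        seq = genome["chrSim"]
        motif_ids = [p.motif_id for p in pfms]
        hits = []
        for pfm in pfms:
            hits.extend(scan(seq, pfm_to_pwm(pfm), 0.8, region_id="chrSim"))
        windows = window_features(hits, len(seq), "chrSim", motif_ids)
        mask = np.zeros(len(seq), dtype=bool)
        for c in truth:
            mask[c.start : c.end] = True
        pos = [w for w in windows if mask[w.start : w.end].mean() > 0.5]
        neg = [w for w in windows if mask[w.start : w.end].mean() == 0.0]
        model = train_lra(pos, neg, motif_ids, seed=1)
        scores = np.array([model.score(w) for w in pos + neg])
        labels = np.array([1] * len(pos) + [0] * len(neg))
        assert roc_auc(scores, labels).auc >= 0.9


class TestConservationFilter:
    def _preds(self):
        from crmkit.crm_predict import CRMPrediction

        return [CRMPrediction("r", 0, 50, 0.9), CRMPrediction("r", 50, 100, 0.9)]

    def test_zero_cutoff_identity(self):
        track = ScoreTrack("chrSim", 0, np.linspace(0, 1, 100))
        preds = self._preds()
        assert conservation_filter(preds, track, 0.0) == preds

    def test_unattainable_cutoff_empties(self):
        track = ScoreTrack("chrSim", 0, np.linspace(0, 1, 100))
        assert conservation_filter(self._preds(), track, 1.01) == []

    def test_filter_never_hurts_auc_on_elevated_tracks(self):
        improved = 0
        for seed in range(5):
            cfg = SimConfig(seed=seed, genome_length=20_000, n_crm=8)
            genome, truth = gen_genome(cfg)
            bounded, _ = gen_conservation_track(truth, cfg)
            seq = genome["chrSim"]
            mask = np.zeros(len(seq), dtype=bool)
            for c in truth:
                mask[c.start : c.end] = True
            starts = np.arange(0, len(seq) - 200 + 1, 50)
            labels = np.array([mask[s : s + 200].mean() > 0.5 for s in starts])
            rng = np.random.default_rng(seed)
            scores = rng.random(len(starts))  # uninformative predictor
            maxcons = np.array([bounded.values[s : s + 200].max() for s in starts])
            from crmkit.enrichment_stats import roc_with_conservation_filter

            base = roc_auc(scores, labels).auc
            filt = roc_with_conservation_filter(scores, labels, maxcons, 0.7).auc
            if filt >= base:
                improved += 1
        assert improved == 5
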