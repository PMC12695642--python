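import itertools

import numpy as np
import pytest

from pxct import phantom, synapse
from pxct.synapse import NodeAnnotation


def node(z, y, x, p=1, modality="em", annotator="a0", dendrite=None):
    return NodeAnnotation((z, y, x), p, annotator, modality, dendrite)


def brute_force_clusters(points, radius):
    """Oracle: transitive closure over the pairwise <= radius relation."""
    n = len(points)
    adj = np.zeros((n, n), dtype=bool)
    for i, j in itertools.combinations(range(n), 2):
        adj[i, j] = adj[j, i] = np.linalg.norm(points[i] - points[j]) <= radius
    labels = -np.ones(n, dtype=int)
    current = 0
    for i in range(n):
        if labels[i] >= 0:
            continue
        stack = [i]
        while stack:
            k = stack.pop()
            if labels[k] >= 0:
                continue
            labels[k] = current
            stack.extend(np.nonzero(adj[k])[0])
        current += 1
    return labels


class TestBuildCensus:
    def test_empty(self):
        census = synapse.build_census([], 300.0)
        assert len(census) == 0

    def test_chain_single_link(self):
        nodes = [node(0, 0, 0), node(0, 0, 250), node(0, 0, 500)]
        census = synapse.build_census(nodes, 300.0)
        assert len(census) == 1
        assert len(census.entries[0].member_nodes) == 3

    def test_boundary_just_beyond_radius(self):
        nodes = [node(0, 0, 0), node(0, 0, 301.0)]
        assert len(synapse.build_census(nodes, 300.0)) == 2
        nodes = [node(0, 0, 0), node(0, 0, 300.0)]
        assert len(synapse.build_census(nodes, 300.0)) == 1

    def test_first_pass_is_min(self):
        nodes = [node(0, 0, 0, p=3), node(0, 0, 100, p=2)]
        census = synapse.build_census(nodes, 300.0)
        assert census.entries[0].first_pass_detected == 2

    def test_matches_brute_force_oracle(self, rng):
        pts = rng.uniform(0, 3000, size=(60, 3))
        nodes = [node(*p) for p in pts]
        census = synapse.build_census(nodes, 300.0)
        labels = brute_force_clusters(pts, 300.0)
        assert len(census) == len(np.unique(labels))
        sizes_a = sorted(len(e.member_nodes) for e in census.entries)
        sizes_b = sorted(np.bincount(labels))
        assert sizes_a == sizes_b

    def test_permutation_invariance(self, rng):
        pts = rng.uniform(0, 2000, size=(40, 3))
        nodes = [node(*p) for p in pts]
        census_a = synapse.build_census(nodes, 300.0)
        perm = rng.permutation(40)
        census_b = synapse.build_census([nodes[i] for i in perm], 300.0)
        np.testing.assert_allclose(census_a.centroids, census_b.centroids)

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            synapse.build_census([], 0.0)


class TestMatchDetections:
    def _census(self, rng, n=50):
        pts = rng.uniform(0, 50_000, size=(n, 3))  # well separated on average
        return synapse.build_census([node(*p) for p in pts], 300.0)

    def test_query_at_centroids_all_detected(self, rng):
        census = self._census(rng)
        queries = [node(*c, modality="pxct") for c in census.centroids]
        detected, unmatched, _ = synapse.match_detections(census, queries, 300.0)
        assert detected.all()
        assert unmatched == []

    def test_no_queries(self, rng):
        census = self._census(rng)
        detected, unmatched, passes = synapse.match_detections(census, [], 300.0)
        assert not detected.any() and unmatched == []
        assert all(p is None for p in passes)

    def test_constructed_sixty_percent(self, rng):
        census = self._census(rng, n=50)
        queries = []
        for i, c in enumerate(census.centroids):
            if i % 5 < 3:  # 30 of 50 = 60%
                offset = rng.standard_normal(3)
                offset *= rng.uniform(100, 290) / np.linalg.norm(offset)
                queries.append(node(*(c + offset), modality="pxct"))
        detected, _, _ = synapse.match_detections(census, queries, 300.0)
        assert detected.mean() == pytest.approx(0.6)

    def test_monotone_in_radius(self, rng):
        census = self._census(rng)
        queries = [
            node(*(c + rng.uniform(-400, 400, 3)), modality="pxct")
            for c in census.centroids
        ]
        counts = [
            synapse.match_detections(census, queries, r)[0].sum()
            for r in (100.0, 300.0, 600.0)
        ]
        assert counts[0] <= counts[1] <= counts[2]


class TestFindHotspots:
    def test_isolated_nodes_no_hotspots(self):
        nodes = [node(0, 0, i * 1000.0) for i in range(5)]
        assert synapse.find_hotspots(nodes, 300.0) == []

    def test_pair_forms_hotspot(self):
        nodes = [node(0, 0, 0), node(0, 0, 200.0)]
        spots = synapse.find_hotspots(nodes, 300.0)
        assert len(spots) == 1 and spots[0]["size"] == 2

    def test_matches_brute_force(self, rng):
        pts = rng.uniform(0, 4000, size=(50, 3))
        nodes = [node(*p) for p in pts]
        spots = synapse.find_hotspots(nodes, 300.0, min_tags=2)
        labels = brute_force_clusters(pts, 300.0)
        expected = sorted(c for c in np.bincount(labels) if c >= 2)
        assert sorted(s["size"] for s in spots) == expected

    def test_min_tags_validated(self):
        with pytest.raises(ValueError):
            synapse.find_hotspots([], 300.0, min_tags=1)


class TestCleanScores:
    def test_identical_annotators_nothing_dropped(self, rng):
        base = rng.integers(1, 5, size=(50, 1, 2))
        scores = np.repeat(base, 3, axis=1)
        cleaned, kept_regions, dropped, kept_annot = synapse.clean_scores(scores, 0.4)
        assert dropped == []
        assert len(kept_regions) == 50
        np.testing.assert_array_equal(cleaned, scores)

    def test_anticorrelated_annotator_dropped(self, rng):
        n = 60
        truth = rng.integers(1, 5, size=n)
        scores = np.zeros((n, 3, 2), dtype=int)
        scores[:, 0, :] = truth[:, None]
        scores[:, 1, :] = truth[:, None]
        scores[:, 2, :] = (5 - truth)[:, None]  # anti-correlated on EM
        _, _, dropped, kept = synapse.clean_scores(scores, 0.4)
        assert dropped == [2]
        assert kept.tolist() == [0, 1]

    def test_region_cleanup_250_to_240(self, rng):
        # mirrors the 250 -> 240 region cleanup arithmetic
        scores = np.repeat(rng.integers(1, 5, size=(250, 1, 2)), 3, axis=1)
        zero_rows = rng.choice(250, size=10, replace=False)
        scores[zero_rows, 1, 1] = 0  # one missing response in 10 regions
        cleaned, kept, dropped, _ = synapse.clean_scores(scores, 0.4)
        assert dropped == []
        assert len(kept) == 240
        assert cleaned.shape == (240, 3, 2)
        assert not np.isin(zero_rows, kept).any()

    def test_too_few_annotators_raises(self, rng):
        n = 40
        truth = rng.integers(1, 5, size=n)
        scores = np.zeros((n, 2, 2), dtype=int)
        scores[:, 0, :] = truth[:, None]
        scores[:, 1, :] = (5 - truth)[:, None]
        with pytest.raises(ValueError, match="fewer than 2"):
            synapse.clean_scores(scores, 0.4)

    def test_invalid_values(self):
        with pytest.raises(ValueError):
            synapse.clean_scores(np.full((5, 3, 2), 7), 0.4)


class TestCaptchaConfusion:
    def test_perfect_agreement(self, rng):
        scores = np.repeat(rng.integers(1, 5, size=(40, 1, 1)), 3, axis=1)
        scores = np.concatenate([scores, scores], axis=2)
        summary, table = synapse.captcha_confusion(scores)
        assert summary.precision == summary.recall == summary.f1 == 1.0
        assert np.all(table == np.diag(np.diag(table)))

    def test_printed_formula_numbers(self):
        # TP=13, FP=3, FN=7 -> P=0.8125, R=0.65, F1=0.7222, F2=0.6771
        s = synapse.ConfusionSummary(tp=13, fp=3, fn=7, tn=10, beta=2.0)
        assert s.precision == pytest.approx(0.8125)
        assert s.recall == pytest.approx(0.65)
        assert s.f1 == pytest.approx(0.7222, abs=1e-4)
        assert s.f_beta == pytest.approx(0.6771, abs=1e-4)

    def test_confusion_from_constructed_scores_equals_counting(self, rng):
        n = 80
        scores = rng.integers(1, 5, size=(n, 3, 2))
        summary, _ = synapse.captcha_confusion(scores)
        em = scores[:, :, 0].mean(axis=1) >= 2.5
        px = scores[:, :, 1].mean(axis=1) >= 2.5
        assert summary.tp == int(np.sum(em & px))
        assert summary.fp == int(np.sum(~em & px))
        assert summary.fn == int(np.sum(em & ~px))
        assert summary.tn == int(np.sum(~em & ~px))

    def test_degenerate_all_low_prediction(self):
        scores = np.zeros((10, 3, 2), dtype=int)
        scores[:, :, 0] = 4  # EM says synapse everywhere
        scores[:, :, 1] = 1  # prediction all negative
        summary, _ = synapse.captcha_confusion(scores)
        assert summary.recall == 0.0
        assert summary.precision is None and summary.precision_undefined

    def test_tie_at_cut_is_synapse(self):
        scores = np.zeros((1, 2, 2), dtype=int)
        scores[0, :, 0] = [2, 3]  # mean 2.5 -> synapse
        scores[0, :, 1] = [2, 3]
        summary, _ = synapse.captcha_confusion(scores)
        assert summary.tp == 1

    def test_rounding_ties_away_from_zero(self):
        scores = np.zeros((1, 2, 2), dtype=int)
        scores[0, :, 0] = [1, 2]  # mean 1.5 -> bin 2
        scores[0, :, 1] = [3, 4]  # mean 3.5 -> bin 4
        _, table = synapse.captcha_confusion(scores)
        assert table[1, 3] == 1

    def test_f_beta_properties(self):
        s = synapse.ConfusionSummary(tp=10, fp=2, fn=8, tn=5, beta=1.0)
        assert s.f_beta == pytest.approx(s.f1)
        high_p = synapse.ConfusionSummary(tp=10, fp=1, fn=10, tn=5, beta=2.0)
        assert high_p.precision > high_p.recall
        assert high_p.f_beta < high_p.f1
        high_r = synapse.ConfusionSummary(tp=10, fp=10, fn=1, tn=5, beta=2.0)
        assert high_r.precision < high_r.recall
        assert high_r.f_beta > high_r.f1

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            synapse.captcha_confusion(np.empty((0, 3, 2)))


class TestDendriteReport:
    @staticmethod
    def make_census_nodes(n_total, first_pass, third_pass=0, spacing=10_000.0):
        nodes = []
        for i in range(n_total):
            if i < first_pass:
                p = 1
            elif i < n_total - third_pass:
                p = 2
            else:
                p = 3
            nodes.append(node(0, 0, i * spacing, p=p))
        return nodes

    def test_printed_census_fractions(self):
        # 273/338 first pass -> 81%; 65/338 third pass -> 19%
        em_nodes = self.make_census_nodes(338, 273, third_pass=65)
        report = synapse.dendrite_report(em_nodes, [], 300.0)
        assert report["census_size"] == 338
        assert report["em_first_pass_pct"] == 81
        assert report["em_third_pass_pct"] == 19

    def test_printed_matched_fractions(self):
        em_nodes = self.make_census_nodes(338, 273, third_pass=65)
        px_nodes = []
        for i in range(225):  # 148 first-pass detections, 77 later
            p = 1 if i < 148 else 2
            px_nodes.append(node(0, 100.0, i * 10_000.0, p=p, modality="pxct"))
        report = synapse.dendrite_report(em_nodes, px_nodes, 300.0)
        assert report["matched_detections"] == 225
        assert report["px_first_pass_pct"] == 66
        assert report["px_later_pass_pct"] == 34

    def test_single_pass_fixture(self):
        em_nodes = self.make_census_nodes(10, 10)
        report = synapse.dendrite_report(em_nodes, [], 300.0)
        assert report["em_first_pass_pct"] == 100

    def test_monte_carlo_recovers_probabilities(self):
        rng = np.random.default_rng(0)
        n = 400
        p_first = 0.7
        nodes = []
        for i in range(n):
            p = 1 if rng.random() < p_first else int(rng.integers(2, 4))
            nodes.append(node(0, 0, i * 10_000.0, p=p))
        report = synapse.dendrite_report(nodes, [], 300.0)
        frac = report["em_first_pass_count"] / report["census_size"]
        # binomial 3-sigma
        assert abs(frac - p_first) < 3 * np.sqrt(p_first * (1 - p_first) / n)

    def test_per_dendrite_stats(self):
        nodes = [
            node(0, 0, i * 10_000.0, p=1, dendrite=i % 2) for i in range(10)
        ]
        px = [node(0, 0, i * 10_000.0, p=1, modality="pxct") for i in range(5)]
        report = synapse.dendrite_report(nodes, px, 300.0)
        assert set(report["per_dendrite"]) == {0, 1}
        total = sum(d["n_census"] for d in report["per_dendrite"].values())
        assert total == 10
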