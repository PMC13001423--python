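import itertools

import numpy as np
import pytest

from ncibind.benchmarks import ID_BENCHMARK, best_baseline_brhr, brhr_gaps
from ncibind.metrics import (
    audit_split,
    binary_metrics,
    brhr_at_k,
    build_split,
    dataset_brhr,
    expected_random_ihr,
    ihr_at_k,
    ligand_similarity,
    protein_similarity,
    simulate_random_ihr,
    stratified_kfold,
    tanimoto,
    top_k_indices,
)


class TestBRHR:
    def test_top1_hit(self):
        scores = np.array([0.1, 0.9, 0.3])
        assert brhr_at_k(scores, {2}, 1) == 1
        assert brhr_at_k(scores, {1}, 1) == 0

    def test_rank_four_needs_k_five(self):
        scores = np.array([0.9, 0.8, 0.7, 0.6, 0.5])
        assert brhr_at_k(scores, {4}, 3) == 0
        assert brhr_at_k(scores, {4}, 5) == 1

    def test_ties_break_to_lower_position(self):
        scores = np.zeros(6)
        assert top_k_indices(scores, 2).tolist() == [0, 1]
        assert brhr_at_k(scores, {1}, 1) == 1
        assert brhr_at_k(scores, {6}, 1) == 0

    def test_matches_bruteforce_on_random_vectors(self, rng):
        pairs = []
        expected_hits = {1: 0, 3: 0, 5: 0}
        for _ in range(200):
            scores = rng.random(20)
            truth = set((rng.choice(20, size=3, replace=False) + 1).tolist())
            pairs.append((scores, truth))
            ranked = sorted(range(20), key=lambda j: (-scores[j], j))
            for k in expected_hits:
                if truth & {j + 1 for j in ranked[:k]}:
                    expected_hits[k] += 1
        for k, hits in expected_hits.items():
            assert dataset_brhr(pairs, k) == pytest.approx(hits / 200)

    def test_monotone_in_k(self, rng):
        scores = rng.random(15)
        truth = {5, 11}
        vals = [brhr_at_k(scores, truth, k) for k in range(1, 16)]
        assert all(a <= b for a, b in zip(vals, vals[1:]))

    def test_empty_truth_excluded_with_warning(self):
        with pytest.warns(UserWarning):
            val = dataset_brhr([(np.array([1.0, 0.0]), {1}),
                                (np.array([1.0, 0.0]), set())], 1)
        assert val == 1.0


class TestIHR:
    def test_argmax_cell_hit(self):
        A = np.zeros((3, 4))
        A[1, 2] = 5.0
        assert ihr_at_k(A, {(2, 3)}, 1) == 1
        assert ihr_at_k(A, {(1, 1)}, 1) == 0

    def test_monotone_in_k(self, rng):
        A = rng.random((5, 8))
        truth = {(2, 3), (5, 8)}
        vals = [ihr_at_k(A, truth, k) for k in range(1, 41)]
        assert all(a <= b for a, b in zip(vals, vals[1:]))
        assert vals[-1] == 1

    def test_closed_form_random_baseline(self):
        # 35 ligand atoms x 368 residues with 3 annotated contacts
        assert 35 * 368 == 12880
        p = expected_random_ihr(35, 368, 3, k=1)
        assert p == pytest.approx(3 / 12880)
        assert round(100 * p, 3) == 0.023
        assert expected_random_ihr(2, 2, 4, k=1) == 1.0

    def test_simulation_agrees_with_closed_form(self):
        rng = np.random.default_rng(11)
        truth = {(1, 1), (7, 100), (35, 368)}
        trials = 20000
        p = 3 / 12880
        est = simulate_random_ihr(35, 368, truth, trials=trials, k=1, rng=rng)
        se = np.sqrt(p * (1 - p) / trials)
        assert abs(est - p) <= 3 * se

    def test_k3_simulation_against_closed_form(self):
        rng = np.random.default_rng(5)
        truth = {(1, 1), (2, 2)}
        est = simulate_random_ihr(4, 5, truth, trials=4000, k=3, rng=rng)
        p = expected_random_ihr(4, 5, 2, k=3)
        se = np.sqrt(p * (1 - p) / 4000)
        assert abs(est - p) <= 3.5 * se


class TestBinaryMetrics:
    def test_perfect_separation(self):
        out = binary_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert out == {"acc": 1.0, "auroc": 1.0, "auprc": 1.0, "f1": 1.0}

    def test_shuffled_labels_near_chance(self, rng):
        p = rng.random(2000)
        y = rng.integers(0, 2, size=2000)
        out = binary_metrics(p, y)
        assert abs(out["auroc"] - 0.5) < 0.05

    def test_auroc_matches_rank_statistic(self):
        p = [0.1, 0.4, 0.35, 0.8, 0.65, 0.2]
        y = [0, 0, 1, 1, 1, 0]
        pairs = [(pi, pj) for pi, yi in zip(p, y) if yi == 1
                 for pj, yj in zip(p, y) if yj == 0]
        mw = np.mean([1.0 if a > b else 0.5 if a == b else 0.0 for a, b in pairs])
        assert binary_metrics(p, y)["auroc"] == pytest.approx(mw)

    def test_monotone_transform_invariance(self, rng):
        p = rng.random(50)
        y = (rng.random(50) < 0.4).astype(int)
        a1 = binary_metrics(p, y)["auroc"]
        a2 = binary_metrics(np.exp(3 * p), y)["auroc"]
        assert a1 == pytest.approx(a2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            binary_metrics([0.5, 0.6], [1, 1])


class TestSimilarity:
    def test_identical_molecules(self):
        assert ligand_similarity("CCO", "OCC") == 1.0

    def test_disjoint_fingerprints(self):
        assert ligand_similarity("C", "O") == 0.0

    def test_hand_built_bit_sets(self):
        assert tanimoto({1, 2, 3, 4, 5}, {3, 4, 5, 6, 7}) == pytest.approx(3 / 7)

    def test_invalid_smiles_rejected(self):
        with pytest.raises(ValueError):
            ligand_similarity("((((", "CC")

    def test_identical_sequences_full_identity(self):
        assert protein_similarity("MKTAYIAK", "MKTAYIAK") == 100.0

    def test_fully_mismatched(self):
        assert protein_similarity("AAAA", "TTTT") == 0.0

    @pytest.mark.parametrize("a,b", [("ACGT", "AGT"), ("MKT", "MGTA"),
                                     ("AAAB", "ABAB"), ("QWERTY", "QWTY")])
    def test_score_matches_exhaustive_alignment_enumeration(self, a, b):
        # enumerate every global alignment (<= 6 residues) and take the best
        # score under match=1 / mismatch=0 / gap=-1
        best = -np.inf

        def walk(i, j, score):
            nonlocal best
            if i == len(a) and j == len(b):
                best = max(best, score)
                return
            if i < len(a) and j < len(b):
                walk(i + 1, j + 1, score + (1 if a[i] == b[j] else 0))
            if i < len(a):
                walk(i + 1, j, score - 1)
            if j < len(b):
                walk(i, j + 1, score - 1)

        walk(0, 0, 0.0)
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score, aligner.mismatch_score = 1, 0
        aligner.open_gap_score = aligner.extend_gap_score = -1
        assert aligner.score(a, b) == pytest.approx(best)
        # and the reported identity corresponds to a valid optimal alignment
        ident = protein_similarity(a, b)
        assert 0.0 <= ident <= 100.0


class TestSplits:
    def test_dissimilar_items_split_by_ratio(self):
        sim = np.zeros((10, 10))
        spec = build_split(10, list(range(10)), sim, "ligand", threshold=0.3,
                           test_fraction=0.3, seed=0)
        assert len(spec.test_pairs) == 3
        assert spec.realized["within_threshold"]

    def test_identical_items_never_separated(self):
        sim = np.zeros((4, 4))
        sim[0, 1] = sim[1, 0] = 100.0  # two identical proteins
        for seed in range(5):
            spec = build_split(4, list(range(4)), sim, "protein", threshold=99.0,
                               test_fraction=0.5, seed=seed)
            side0 = 0 in {spec.item_of_pair[k] for k in spec.test_pairs}
            side1 = 1 in {spec.item_of_pair[k] for k in spec.test_pairs}
            assert side0 == side1

    def test_planted_clusters_pass_posthoc_audit(self, rng):
        n = 60
        labels = rng.integers(0, 12, size=n)
        sim = rng.uniform(0, 0.25, size=(n, n))
        for i in range(n):
            for j in range(n):
                if labels[i] == labels[j]:
                    sim[i, j] = rng.uniform(0.7, 1.0)
        sim = (sim + sim.T) / 2
        np.fill_diagonal(sim, 1.0)
        spec = build_split(n, list(range(n)), sim, "ligand", threshold=0.5,
                           test_fraction=0.25, seed=1)
        audit = audit_split(spec, sim)
        # exhaustive all-pairs audit on the controlled axis
        test_items = {spec.item_of_pair[k] for k in spec.test_pairs}
        worst = max(sim[i, j] for i in range(n) for j in range(n)
                    if (i in test_items) != (j in test_items))
        assert audit["peak"] == pytest.approx(worst)
        assert audit["peak"] <= 0.5

    def test_giant_cluster_is_infeasible(self):
        sim = np.full((5, 5), 0.9)
        with pytest.raises(ValueError, match="blocking cluster"):
            build_split(5, list(range(5)), sim, "protein", threshold=0.5)

    def test_kfold_is_disjoint_and_stratified(self):
        labels = [0] * 20 + [1] * 20
        folds = stratified_kfold(labels, n_folds=5, seed=0)
        assert len(folds) == 5
        for tr, te in folds:
            assert set(tr).isdisjoint(te)
            assert sum(labels[i] for i in te) == 4


class TestPublishedGaps:
    def test_localization_gaps_from_reference_table(self):
        assert best_baseline_brhr(1) == 16.1
        assert best_baseline_brhr(3) == 23.9
        assert best_baseline_brhr(5) == 31.4
        assert brhr_gaps() == {1: pytest.approx(39.5), 3: pytest.approx(45.6),
                               5: pytest.approx(43.2)}

    def test_supervised_row_leads_every_binary_metric(self):
        sup = ID_BENCHMARK["supervised"]
        for metric in ("acc", "auprc", "auroc", "f1"):
            assert all(sup[metric] > v[metric] for name, v in ID_BENCHMARK.items()
                       if name != "supervised")
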