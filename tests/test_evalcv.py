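"""Consistency scoring, identity clustering, folds, PR evaluation."""

import numpy as np
import pytest
from scipy import stats

from conftest import family_alignment
from dombind.bindfreq import DistanceProfile, build_distance_profile
from dombind.domhits import DomainHit
from dombind.evalcv import (
    PRCurve,
    alignment_identity,
    assign_folds,
    cluster_by_identity,
    confident_threshold,
    consistency_pcc,
    cross_validate,
    pairwise_identity,
    pr_curve,
)
from dombind.fixtures import FamilySpec, build_family

pytestmark = pytest.mark.timeout(300)


class TestConsistencyPCC:
    def test_identical_geometry_scores_one(self):
        fam = build_family(
            FamilySpec(n_instances=6, mutation_rate=0.3, distance_noise_sd=0.0,
                       seed=3)
        )
        prof = build_distance_profile(fam.instances, "SMALL_MOLECULE")
        assert consistency_pcc(prof, reps=5, seed=0) == pytest.approx(1.0)

    def test_scale_invariance_of_pearson(self):
        # fold means (1,2,3) vs (2,4,6): perfectly linear -> PCC 1
        prof = DistanceProfile(
            "PF1", "ION",
            {1: [("a", 1.0), ("b", 2.0)], 2: [("a", 2.0), ("b", 4.0)],
             3: [("a", 3.0), ("b", 6.0)]},
            ["a", "b"],
        )
        assert consistency_pcc(prof, reps=3, seed=0) == pytest.approx(1.0)

    def test_matches_hand_computation_on_seeded_split(self):
        fam = build_family(FamilySpec(n_instances=6, seed=17))
        prof = build_distance_profile(fam.instances, "SMALL_MOLECULE")
        got = consistency_pcc(prof, reps=1, seed=99)
        # replay the same seeded split by hand
        mat, _ = prof.distance_matrix()
        rng = np.random.default_rng(99)
        perm = rng.permutation(len(prof.instance_ids))
        half = len(prof.instance_ids) // 2
        va = np.nanmean(mat[perm[:half]], axis=0)
        vb = np.nanmean(mat[perm[half:]], axis=0)
        expected = stats.pearsonr(va, vb).statistic
        assert got == pytest.approx(expected, abs=1e-12)

    def test_too_few_instances_rejected(self):
        prof = DistanceProfile("PF1", "ION", {1: [("a", 1.0)]}, ["a"])
        with pytest.raises(ValueError):
            consistency_pcc(prof)


class TestIdentity:
    def _hit(self, state_map):
        return DomainHit("q", "PF1", 50.0, state_map)

    def test_identical_instances(self):
        h = self._hit({1: 1, 2: 2, 3: 3})
        assert pairwise_identity(h, "ACD", h, "ACD") == 1.0

    def test_nine_of_ten_columns(self):
        sm = {i: i for i in range(1, 11)}
        a, b = "ACDEFHIKLM", "ACDEFHIKLW"
        assert pairwise_identity(self._hit(sm), a, self._hit(sm), b) == pytest.approx(0.9)

    def test_disjoint_state_maps_give_zero(self):
        a = self._hit({1: 1, 2: 2})
        b = self._hit({3: 1, 4: 2})
        assert pairwise_identity(a, "AC", b, "AC") == 0.0

    def test_accession_mismatch_rejected(self):
        a = self._hit({1: 1})
        b = DomainHit("q", "PF2", 50.0, {1: 1})
        with pytest.raises(ValueError):
            pairwise_identity(a, "A", b, "A")

    def test_alignment_identity_ignores_gap_columns(self):
        assert alignment_identity("AC-D", "ACE-") == pytest.approx(1.0)
        assert alignment_identity("--", "AC") == 0.0


class TestClusterByIdentity:
    def test_identical_instances_form_one_group(self):
        groups = cluster_by_identity({f"i{k}": "ACDE" for k in range(4)})
        assert len(groups) == 1

    def test_single_linkage_is_transitive(self):
        rows = {
            "A": "AAAAAAAAAAAAAAAAAAAA",
            "B": "AAAAAAAAAAAAAAAAAAAC",  # 19/20 = 0.95 vs A
            "C": "CAAAAAAAAAAAAAAAAAAC",  # 0.95 vs B but only 0.90 vs A
            "D": "CCCCCCCCCCCCCCCCCCCC",  # far from everything
        }
        assert alignment_identity(rows["A"], rows["B"]) == pytest.approx(0.95)
        assert alignment_identity(rows["B"], rows["C"]) == pytest.approx(0.95)
        assert alignment_identity(rows["A"], rows["C"]) == pytest.approx(0.90)
        # A-C linked only through B: single linkage merges the chain
        groups = {frozenset(g) for g in cluster_by_identity(rows, threshold=0.95)}
        assert groups == {frozenset({"A", "B", "C"}), frozenset({"D"})}

    def test_all_dissimilar_gives_singletons(self):
        rows = {"A": "AAAA", "B": "CCCC", "C": "DDDD"}
        groups = cluster_by_identity(rows, threshold=0.9)
        assert sorted(map(len, groups)) == [1, 1, 1]

    def test_between_group_identity_below_threshold(self, noisy_family):
        align = family_alignment(noisy_family)
        groups = cluster_by_identity(align, threshold=0.90)
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for a in groups[gi]:
                    for b in groups[gj]:
                        assert alignment_identity(align[a], align[b]) < 0.90


class TestAssignFolds:
    def test_25_units_into_10_balanced_folds(self):
        fa = assign_folds([f"u{i}" for i in range(25)], k_max=10, seed=0)
        sizes = sorted(len(v) for v in fa.folds().values())
        assert sizes == [2] * 5 + [3] * 5
        assert fa.k == 10

    def test_fewer_units_than_folds_gives_singletons(self):
        fa = assign_folds(list("abcd"), k_max=10, seed=0)
        assert fa.k == 4
        assert all(len(v) == 1 for v in fa.folds().values())

    def test_deterministic_under_seed(self):
        units = [f"u{i}" for i in range(12)]
        assert assign_folds(units, seed=5).fold_of == assign_folds(units, seed=5).fold_of

    def test_single_unit_rejected(self):
        with pytest.raises(ValueError):
            assign_folds(["one"])


class TestPRCurve:
    def test_perfect_separation_gives_auprc_one(self):
        c = pr_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert c.auprc == pytest.approx(1.0)

    def test_constant_scores_collapse_to_baseline_point(self):
        c = pr_curve([0.5] * 6, [1, 0, 1, 0, 0, 0])
        assert len(c.thresholds) == 1
        assert c.precision[0] == pytest.approx(c.baseline)
        assert c.auprc == pytest.approx(c.baseline)

    def test_hand_enumerated_average_precision(self):
        scores = [0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2]
        labels = [1, 1, 0, 1, 0, 0, 0, 0]
        c = pr_curve(scores, labels)
        assert c.auprc == pytest.approx((1 + 1 + 0.75) / 3, abs=1e-12)
        assert c.baseline == pytest.approx(3 / 8)

    def test_recalls_nondecreasing_and_threshold_enumeration_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 60))
            scores = rng.choice(np.round(rng.uniform(size=8), 2), size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.sum() == 0:
                labels[0] = 1
            c = pr_curve(scores, labels)
            assert all(r2 >= r1 for r1, r2 in zip(c.recall, c.recall[1:]))
            # brute force over all distinct thresholds
            ap = 0.0
            prev_recall = 0.0
            n_pos = labels.sum()
            for t in sorted(set(scores), reverse=True):
                pred = scores >= t
                prec = labels[pred].sum() / pred.sum()
                rec = labels[pred].sum() / n_pos
                ap += prec * (rec - prev_recall)
                prev_recall = rec
            assert c.auprc == pytest.approx(ap, abs=1e-9)

    def test_agrees_with_sklearn_average_precision(self, rng):
        from sklearn.metrics import average_precision_score

        for _ in range(10):
            n = int(rng.integers(5, 80))
            scores = np.round(rng.uniform(size=n), 2)
            labels = rng.integers(0, 2, size=n)
            if labels.sum() == 0:
                labels[0] = 1
            c = pr_curve(scores, labels)
            assert c.auprc == pytest.approx(
                average_precision_score(labels, scores), abs=1e-9
            )


class TestCrossValidate:
    def _run(self, fam, mode="per_fold", labels=None, k_max=10, seed=0):
        prof = build_distance_profile(fam.instances, "SMALL_MOLECULE")
        align = family_alignment(fam)
        folds = assign_folds(prof.instance_ids, k_max=k_max, seed=seed)
        return cross_validate(prof, align, folds, labels=labels, mode=mode)

    def test_planted_interface_recovers_perfect_auprc(self, clean_family):
        curve = self._run(clean_family)
        assert curve.auprc == pytest.approx(1.0)
        expected_baseline = len(clean_family.spec.binding_states) / clean_family.spec.n_states
        assert curve.baseline == pytest.approx(expected_baseline)

    def test_annotation_labels_match_contact_labels_on_fixture(self, clean_family):
        fam = clean_family
        prof = build_distance_profile(fam.instances, "SMALL_MOLECULE")
        label_map = {}
        for hit, st, lig in fam.instances:
            from dombind.bindfreq import instance_key

            binding = fam.annotation[st.entry_id]
            label_map[instance_key(st, hit, lig)] = {
                s for s, p in hit.state_map.items() if p in binding
            }
        a = self._run(fam, labels=label_map)
        b = self._run(fam, labels=None)
        assert a.auprc == pytest.approx(b.auprc, abs=1e-12)

    def test_pooled_and_per_fold_agree_on_perfect_scores(self, clean_family):
        assert self._run(clean_family, mode="pooled").auprc == pytest.approx(1.0)

    def test_identity_groups_never_straddle_folds(self):
        fam = build_family(FamilySpec(n_instances=8, mutation_rate=0.3, seed=21))
        prof = build_distance_profile(fam.instances, "SMALL_MOLECULE")
        align = family_alignment(fam)
        groups = cluster_by_identity(align, threshold=0.90)
        gmap = {f"g{k}": list(g) for k, g in enumerate(groups)}
        assert len(gmap) >= 2  # divergent sequences split into several groups
        folds = assign_folds(sorted(gmap), k_max=10, seed=0, mode="identity90")
        curve = cross_validate(prof, align, folds, groups=gmap)
        assert 0.0 <= curve.auprc <= 1.0
        for gid, members in gmap.items():
            assert len({folds.fold_of[gid]}) == 1  # group maps to one fold

    def test_random_scorer_auprc_near_baseline(self):
        # scores carrying no signal: AUPRC concentrates near the positive rate
        rng = np.random.default_rng(0)
        aps = []
        for _ in range(200):
            labels = rng.integers(0, 2, size=40)
            if labels.sum() == 0:
                labels[0] = 1
            scores = rng.uniform(size=40)
            aps.append(pr_curve(scores, labels).auprc)
        assert np.mean(aps) == pytest.approx(0.5, abs=0.05)


class TestConfidentThreshold:
    def _curve(self, scores, labels):
        return pr_curve(scores, labels)

    def test_all_positives_first_threshold_is_lowest_positive(self):
        c = self._curve([0.9, 0.8, 0.7, 0.3, 0.2], [1, 1, 1, 0, 0])
        ci = confident_threshold(c, 0.5)
        assert ci.threshold == pytest.approx(0.7)
        assert ci.achieved_precision == pytest.approx(1.0)

    def test_high_baseline_predicts_everything(self):
        # lowest-scored item is a positive: the qualifying max-recall
        # threshold is the minimum score, i.e. everything predicted
        c = self._curve([0.9, 0.6, 0.3, 0.1], [1, 0, 1, 1])
        ci = confident_threshold(c, 0.5)
        assert ci.threshold == pytest.approx(0.1)

    def test_derived_curve_picks_highest_precision_at_full_recall(self):
        c = self._curve([0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2],
                        [1, 1, 0, 1, 0, 0, 0, 0])
        ci = confident_threshold(c, 0.5)
        assert ci.threshold == pytest.approx(0.6)
        assert ci.achieved_precision == pytest.approx(0.75)

    def test_none_when_no_threshold_qualifies(self):
        c = self._curve([0.9, 0.8, 0.7, 0.6], [0, 0, 0, 1])
        assert confident_threshold(c, 0.9) is None
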