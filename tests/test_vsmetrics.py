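import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from gutdock.errors import InputError, MetricUndefinedError
from gutdock.synthfix import PlantedEnrichmentSpec, gen_scored_library
from gutdock.vsmetrics import (
    ScoredLibrary,
    bedroc,
    bedroc_bounds,
    enrichment_factor,
    enrichment_report,
    roc_auc,
)

import oracles


def library(scores, labels, direction="lower_better", ids=None):
    ids = ids or [f"c{i:03d}" for i in range(len(scores))]
    return ScoredLibrary(
        ids=tuple(ids),
        scores=np.asarray(scores, float),
        is_active=np.asarray(labels, bool),
        score_direction=direction,
    )


def random_library(rng, n=None):
    n = n or int(rng.integers(10, 101))
    a = int(rng.integers(1, n))
    labels = np.zeros(n, bool)
    labels[rng.choice(n, a, replace=False)] = True
    # duplicated score values exercise the tie policies
    scores = np.round(rng.normal(size=n), 1)
    return library(scores, labels)


class TestEnrichmentFactor:
    def test_front_loaded_hand_value(self):
        # 10 actives occupying ranks 1..10 of 100: EF10% = (10/10)/(10/100)
        scores = np.concatenate([np.arange(10) - 100.0, np.arange(90)])
        labels = [True] * 10 + [False] * 90
        assert enrichment_factor(library(scores, labels), 0.10) == 10.0

    def test_whole_list_is_one(self, rng):
        lib = random_library(rng)
        assert enrichment_factor(lib, 1.0) == pytest.approx(1.0)

    def test_matches_counting_oracle(self, rng):
        for _ in range(30):
            lib = random_library(rng, n=30)
            for fraction in (0.01, 0.1, 0.33, 1.0):
                expected = oracles.ef_by_counting(
                    lib.ids, lib.scores, lib.is_active, fraction
                )
                assert enrichment_factor(lib, fraction) == pytest.approx(
                    expected, abs=1e-12
                )

    def test_recall_convention(self):
        scores = np.concatenate([np.arange(10) - 100.0, np.arange(90)])
        labels = [True] * 10 + [False] * 90
        lib = library(scores, labels)
        assert enrichment_factor(lib, 0.10, convention="recall") == 10.0
        # half the actives in the top 10%: recall form gives 5 / 0.1 / 10
        scores2 = np.concatenate(
            [np.arange(5) - 100.0, np.arange(95, dtype=float)]
        )
        labels2 = [True] * 5 + [False] * 5 + [True] * 5 + [False] * 85
        lib2 = library(scores2, labels2)
        assert enrichment_factor(lib2, 0.10, convention="recall") == 5.0

    def test_undefined_without_both_classes(self):
        with pytest.raises(MetricUndefinedError):
            enrichment_factor(library([1.0, 2.0], [True, True]), 0.5)


class TestRocAuc:
    def test_perfect_and_inverted(self):
        lib = library([-3, -2, 1, 2], [True, True, False, False])
        _, auc = roc_auc(lib)
        assert auc == 1.0
        lib_inv = library([-3, -2, 1, 2], [False, False, True, True])
        assert roc_auc(lib_inv)[1] == 0.0

    def test_interleaved_hand_value(self):
        # actives at ranks 1 and 3 of 4: 3 of 4 (active, decoy) pairs won
        lib = library([1.0, 2.0, 3.0, 4.0], [True, False, True, False])
        assert roc_auc(lib)[1] == 0.75

    def test_matches_pairwise_and_sklearn(self, rng):
        for _ in range(30):
            lib = random_library(rng)
            _, auc = roc_auc(lib)
            assert auc == pytest.approx(
                oracles.auc_by_pairs(lib.scores, lib.is_active), abs=1e-12
            )
            assert auc == pytest.approx(
                roc_auc_score(lib.is_active, -lib.scores), abs=1e-12
            )

    def test_trapezoid_equals_auc(self, rng):
        lib = random_library(rng)
        points, auc = roc_auc(lib)
        fpr, tpr = np.array(points).T
        assert np.trapezoid(tpr, fpr) == pytest.approx(auc, abs=1e-12)
        assert points[0] == (0.0, 0.0) and points[-1] == (1.0, 1.0)

    def test_label_swap_complement(self, rng):
        lib = random_library(rng)
        swapped = library(lib.scores, ~lib.is_active, ids=lib.ids)
        assert roc_auc(lib)[1] + roc_auc(swapped)[1] == pytest.approx(1.0)


class TestBedroc:
    def test_front_loaded_equals_closed_form_max(self):
        lib = gen_scored_library(
            PlantedEnrichmentSpec(separation=50.0, seed=7)
        )
        _, best = bedroc_bounds(lib.N, lib.A, alpha=20.0)
        assert bedroc(lib, alpha=20.0) == pytest.approx(best, abs=1e-12)

    def test_single_active_last_small_case(self):
        lib = library([1.0, 2, 3, 4, 5], [False] * 4 + [True])
        n, alpha = 5, 20.0
        rie = math.exp(-alpha * 5 / n) / (
            (1 / n) * (1 - math.exp(-alpha)) / (math.exp(alpha / n) - 1)
        )
        scale = (1 / n) * math.sinh(alpha / 2) / (
            math.cosh(alpha / 2) - math.cosh(alpha / 2 - alpha / n)
        )
        expected = rie * scale + 1 / (1 - math.exp(alpha * (1 - 1 / n)))
        assert bedroc(lib) == pytest.approx(expected, abs=1e-12)
        worst, _ = bedroc_bounds(5, 1, alpha=20.0)
        assert bedroc(lib) == pytest.approx(worst, abs=1e-12)

    def test_matches_formula_oracle(self, rng):
        for _ in range(30):
            lib = random_library(rng)
            assert bedroc(lib) == pytest.approx(
                oracles.bedroc_by_formula(lib.scores, lib.is_active),
                abs=1e-12,
            )

    def test_random_permutation_mean(self, rng):
        # analytic expectation under a uniformly random ranking
        n, a, alpha = 510, 10, 20.0
        ra = a / n
        scale = ra * math.sinh(alpha / 2) / (
            math.cosh(alpha / 2) - math.cosh(alpha / 2 - alpha * ra)
        )
        expected = scale + 1 / (1 - math.exp(alpha * (1 - ra)))
        scores = np.arange(n, dtype=float)
        values = []
        for _ in range(1000):
            labels = np.zeros(n, bool)
            labels[rng.choice(n, a, replace=False)] = True
            values.append(bedroc(library(scores, labels)))
        se = np.std(values, ddof=1) / math.sqrt(len(values))
        assert abs(np.mean(values) - expected) < 3 * se

    def test_bounds(self, rng):
        for _ in range(20):
            lib = random_library(rng)
            assert 0.0 <= bedroc(lib) <= 1.0


class TestInvariances:
    @given(st.integers(0, 2**31 - 1))
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        lib = random_library(rng, n=40)
        # strictly increasing map on a lower-better scale keeps the ranking
        transformed = library(
            np.expm1(lib.scores / 10.0) * 3 + 2, lib.is_active, ids=lib.ids
        )
        assert roc_auc(transformed)[1] == pytest.approx(
            roc_auc(lib)[1], abs=1e-9
        )
        assert bedroc(transformed) == pytest.approx(bedroc(lib), abs=1e-9)
        assert enrichment_factor(transformed, 0.1) == pytest.approx(
            enrichment_factor(lib, 0.1)
        )

    def test_direction_flip(self, rng):
        lib = random_library(rng)
        flipped = ScoredLibrary(
            ids=lib.ids, scores=-lib.scores, is_active=lib.is_active,
            score_direction="higher_better",
        )
        assert roc_auc(flipped)[1] == pytest.approx(roc_auc(lib)[1])

    def test_reversed_ranking_not_better(self, rng):
        lib = gen_scored_library(PlantedEnrichmentSpec(seed=3))
        reversed_lib = ScoredLibrary(
            ids=lib.ids, scores=lib.scores, is_active=lib.is_active,
            score_direction="higher_better",
        )
        assert roc_auc(lib)[1] > 0.5
        assert bedroc(reversed_lib) <= bedroc(lib)


class TestEnrichmentReport:
    def test_perfect_planted_library(self):
        lib = gen_scored_library(PlantedEnrichmentSpec(separation=50.0, seed=2))
        report = enrichment_report(lib)
        assert report.auc == 1.0
        assert report.bedroc_alpha20 == pytest.approx(
            bedroc_bounds(lib.N, lib.A)[1], abs=1e-12
        )
        # EF1%: top 5 of 510 are all active -> (5/5)/(10/510)
        assert report.ef1 == pytest.approx(51.0)

    def test_fields_equal_individual_metrics(self, rng):
        lib = random_library(rng, n=20)
        report = enrichment_report(lib)
        assert report.auc == roc_auc(lib)[1]
        assert report.bedroc_alpha20 == bedroc(lib, 20.0)
        assert report.ef1 == enrichment_factor(lib, 0.01)
        assert report.ef5 == enrichment_factor(lib, 0.05)
        assert report.ef10 == enrichment_factor(lib, 0.10)

    def test_shuffled_labels_near_null(self, rng):
        aucs, efs = [], []
        scores = np.arange(510, dtype=float)
        for _ in range(300):
            labels = np.zeros(510, bool)
            labels[rng.choice(510, 10, replace=False)] = True
            lib = library(scores, labels)
            aucs.append(roc_auc(lib)[1])
            efs.append(enrichment_factor(lib, 0.10))
        se = np.std(aucs, ddof=1) / math.sqrt(len(aucs))
        assert abs(np.mean(aucs) - 0.5) < 3 * se
        se_ef = np.std(efs, ddof=1) / math.sqrt(len(efs))
        assert abs(np.mean(efs) - 1.0) < 3 * se_ef


def test_library_validation():
    with pytest.raises(InputError):
        library([1.0], [], ids=["a"])
    with pytest.raises(InputError):
        library([1.0, 2.0], [True, False], ids=["a", "a"])
    with pytest.raises(InputError):
        ScoredLibrary(ids=("a",), scores=np.array([1.0]),
                      is_active=np.array([True]), score_direction="sideways")
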