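import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gutdock.errors import InputError, InsufficientDataError
from gutdock.offtarget import (
    RECEPTORS,
    SITES,
    ClinicalRankTable,
    ScoreMatrix,
    combined_ranking,
    compare_query,
    rank_score_correlation,
)
from gutdock.synthfix import (
    PlantedCorrelationSpec,
    fig3_ranks,
    gen_score_matrix,
    table3_ranks,
)

import oracles


def single_site_matrix(drug_scores, receptor="GCGR", site="orthosteric"):
    return ScoreMatrix.from_dict(
        {(d, receptor, site): s for d, s in drug_scores.items()}
    )


FIVE_DRUGS = ["drug_01", "drug_02", "drug_03", "drug_04", "drug_05"]
FIVE_RANKS = ClinicalRankTable(
    entries={d: i for i, d in enumerate(FIVE_DRUGS, 1)}
)


class TestRankScoreCorrelation:
    def test_perfect_linearity(self):
        matrix = single_site_matrix(
            {d: -10.0 + i for i, d in enumerate(FIVE_DRUGS, 1)}
        )
        res = rank_score_correlation(matrix, FIVE_RANKS)
        assert res.coefficients[("GCGR", "orthosteric")] == pytest.approx(1.0)

    def test_hand_oracle_value(self):
        scores = [-9.0, -8.1, -8.4, -7.2, -7.0]
        matrix = single_site_matrix(dict(zip(FIVE_DRUGS, scores)))
        res = rank_score_correlation(matrix, FIVE_RANKS)
        expected = oracles.pearson_by_hand([1, 2, 3, 4, 5], scores)
        assert res.coefficients[("GCGR", "orthosteric")] == pytest.approx(
            expected, abs=1e-12
        )
        assert res.n_drugs[("GCGR", "orthosteric")] == 5

    def test_spearman_monotone_invariance(self):
        scores = [-9.0, -8.1, -8.4, -7.2, -7.0]
        matrix = single_site_matrix(dict(zip(FIVE_DRUGS, scores)))
        warped = single_site_matrix(
            dict(zip(FIVE_DRUGS, np.exp(np.asarray(scores) / 2)))
        )
        r1 = rank_score_correlation(matrix, FIVE_RANKS, method="spearman")
        r2 = rank_score_correlation(warped, FIVE_RANKS, method="spearman")
        assert r1.coefficients == pytest.approx(r2.coefficients)

    def test_pearson_affine_invariance(self):
        scores = np.array([-9.0, -8.1, -8.4, -7.2, -7.0])
        m1 = single_site_matrix(dict(zip(FIVE_DRUGS, scores)))
        m2 = single_site_matrix(dict(zip(FIVE_DRUGS, 3.0 * scores + 7.0)))
        r1 = rank_score_correlation(m1, FIVE_RANKS)
        r2 = rank_score_correlation(m2, FIVE_RANKS)
        assert r1.coefficients == pytest.approx(r2.coefficients)

    def test_rank_zero_drugs_excluded(self):
        ranks = ClinicalRankTable(
            entries={**FIVE_RANKS.entries, "compound 15": 0}
        )
        matrix = single_site_matrix(
            {**dict(zip(FIVE_DRUGS, [-9.0, -8.1, -8.4, -7.2, -7.0])),
             "compound 15": -10.5}
        )
        res = rank_score_correlation(matrix, ranks)
        assert res.n_drugs[("GCGR", "orthosteric")] == 5

    def test_insufficient_shared_drugs(self):
        matrix = single_site_matrix({"drug_01": -9.0, "drug_02": -8.0})
        with pytest.raises(InsufficientDataError):
            rank_score_correlation(matrix, FIVE_RANKS)

    def test_planted_rho_recovery(self):
        estimates = []
        for rep in range(200):
            matrix, ranks = gen_score_matrix(
                PlantedCorrelationSpec(rho=0.9, seed=1000 + rep)
            )
            res = rank_score_correlation(matrix, ranks)
            estimates.extend(res.coefficients.values())
        se = np.std(estimates, ddof=1) / math.sqrt(len(estimates))
        assert abs(np.mean(estimates) - 0.9) <= max(3 * se, 1e-9)

    def test_replicates_averaged_before_correlating(self):
        matrix = ScoreMatrix.from_dict(
            {(d, "GCGR", "orthosteric"): [-10.0 + i - 0.2, -10.0 + i + 0.2]
             for i, d in enumerate(FIVE_DRUGS, 1)}
        )
        res = rank_score_correlation(matrix, FIVE_RANKS)
        assert res.coefficients[("GCGR", "orthosteric")] == pytest.approx(1.0)


class TestCombinedRanking:
    def reference_matrix(self):
        rows = {}
        for i, d in enumerate(FIVE_DRUGS, 1):
            for rec in RECEPTORS:
                for site in SITES:
                    rows[(d, rec, site)] = -9.0 + 0.5 * i
        return ScoreMatrix.from_dict(rows)

    def query(self, value):
        return {
            (rec, site): value for rec in RECEPTORS for site in SITES
        }

    def test_best_scoring_query_takes_rank_zero(self):
        merged = combined_ranking(
            self.reference_matrix(), FIVE_RANKS, self.query(-12.0),
            query_name="compound 15",
        )
        assert merged[0] == ("compound 15", 0)
        assert merged[1] == ("drug_01", 1)
        assert [r for _, r in merged[1:]] == [1, 2, 3, 4, 5]

    def test_tie_goes_to_reference(self):
        # query mean equals drug_03's mean: placed right after it
        merged = combined_ranking(
            self.reference_matrix(), FIVE_RANKS, self.query(-7.5)
        )
        names = [d for d, _ in merged]
        assert names.index("query") == names.index("drug_03") + 1
        assert [r for _, r in merged] == [1, 2, 3, 4, 5, 6]

    def test_reference_only_order_reproduces_clinical_ranking(self):
        merged = combined_ranking(
            self.reference_matrix(), FIVE_RANKS, self.query(99.0)
        )
        refs = [d for d, _ in merged if d != "query"]
        assert refs == FIVE_DRUGS

    def test_matches_insertion_oracle(self, rng):
        for _ in range(25):
            rows = {
                (d, rec, site): float(rng.normal(-8, 1))
                for d in FIVE_DRUGS for rec in RECEPTORS for site in SITES
            }
            matrix = ScoreMatrix.from_dict(rows)
            q = {(rec, site): float(rng.normal(-8, 1))
                 for rec in RECEPTORS for site in SITES}
            merged = combined_ranking(matrix, FIVE_RANKS, q)
            # naive oracle: count references beating the query on mean score
            ref_mean = {
                d: np.mean([rows[(d, r, s)] for r in RECEPTORS for s in SITES])
                for d in FIVE_DRUGS
            }
            q_mean = np.mean(list(q.values()))
            p = sum(1 for d in FIVE_DRUGS if ref_mean[d] <= q_mean)
            names = [d for d, _ in merged]
            assert names.index("query") == (0 if p == 0 else p)
            if p == 0:
                assert merged[0][1] == 0

    def test_missing_keys_rejected(self):
        with pytest.raises(InputError):
            combined_ranking(
                self.reference_matrix(), FIVE_RANKS,
                {("GCGR", "orthosteric"): -9.0},
            )


class TestCompareQuery:
    def test_replicate_dispersion(self):
        matrix = ScoreMatrix.from_dict(
            {("nebivolol", "GCGR", "orthosteric"): [-8.0, -8.4, -8.2]}
        )
        report = compare_query(
            matrix, {("GCGR", "orthosteric"): [-9.0, -9.4]},
            ranks=fig3_ranks(),
        )
        ref = report[~report.is_query].iloc[0]
        assert ref.mean_score == pytest.approx(-8.2)
        assert ref.score_sd == pytest.approx(
            np.std([-8.0, -8.4, -8.2], ddof=1)
        )
        assert ref.clinical_rank == 2
        q = report[report.is_query].iloc[0]
        assert q.mean_score == pytest.approx(-9.2)

    def test_single_replicate_zero_dispersion(self):
        matrix = ScoreMatrix.from_dict(
            {("atenolol", "GCGR", "allosteric"): -6.5}
        )
        report = compare_query(matrix, {("GCGR", "allosteric"): -7.0})
        assert (report.score_sd == 0.0).all()

    def test_full_matrix_covers_ten_keys(self):
        matrix, ranks = gen_score_matrix(PlantedCorrelationSpec(seed=5))
        q = {(rec, site): -8.5 for rec in RECEPTORS for site in SITES}
        report = compare_query(matrix, q, ranks=ranks)
        keys = set(map(tuple, report[["receptor", "site"]].values))
        assert keys == {(r, s) for r in RECEPTORS for s in SITES}

    def test_empty_query_rejected(self):
        matrix = ScoreMatrix.from_dict(
            {("atenolol", "GCGR", "allosteric"): -6.5}
        )
        with pytest.raises(InputError):
            compare_query(matrix, {})


class TestFixturesAndTypes:
    def test_both_rank_assignments_ship(self):
        fig3 = fig3_ranks()
        t3 = table3_ranks()
        assert fig3.entries["carvedilol"] == 1
        assert fig3.entries["nebivolol"] == 2
        assert fig3.entries["compound 15"] == 0
        assert t3.entries["nebivolol"] == 1
        assert t3.entries["carvedilol"] == 1
        assert t3.entries["metoprolol"] == 4

    def test_negative_rank_rejected(self):
        with pytest.raises(InputError):
            ClinicalRankTable(entries={"x": -1})

    def test_duplicate_matrix_key_rejected(self):
        df = pd.DataFrame(
            [("a", "GCGR", "orthosteric", 1, -8.0),
             ("a", "GCGR", "orthosteric", 1, -8.5)],
            columns=["drug", "receptor", "site", "replicate", "score"],
        )
        with pytest.raises(InputError):
            ScoreMatrix(table=df)

    def test_tsv_roundtrip(self, tmp_path):
        matrix, _ = gen_score_matrix(PlantedCorrelationSpec(seed=9))
        path = tmp_path / "scores.tsv"
        matrix.to_tsv(path)
        back = ScoreMatrix.from_tsv(path)
        pd.testing.assert_frame_equal(matrix.table, back.table)
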