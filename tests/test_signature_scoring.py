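import math
from itertools import combinations

import numpy as np
import pytest

from immunosite.errors import ConfigurationError, ValidationError
from immunosite.io_formats import GeneSet
from immunosite.signature_scoring import (
    ScoringConfig,
    auc_score,
    rank_genes,
    score_matrix,
    ssgsea_score,
)

from conftest import make_matrix


def brute_force_auc(ranking, members, universe, max_rank):
    """Rebuild the recovery curve step by step."""
    member_flags = [universe[i] in members for i in ranking]
    raw = 0
    y = 0
    for x in range(1, max_rank + 1):
        if member_flags[x - 1]:
            y += 1
        raw += y
    n_hits = min(len(set(members) & set(universe)), max_rank)
    best = sum(min(x, n_hits) for x in range(1, max_rank + 1))
    return raw / best


def brute_force_ssgsea(values, members, universe, alpha):
    """Independent running-sum implementation."""
    n = len(universe)
    order = sorted(range(n), key=lambda i: (-values[i], i))
    rank_value = {g: n - pos for pos, g in enumerate(order)}
    in_set = [universe[i] in members for i in order]
    w = [abs(rank_value[g]) ** alpha if in_set[pos] else 0.0 for pos, g in enumerate(order)]
    wsum = sum(w)
    n_out = n - sum(in_set)
    score = 0.0
    cum_in = 0.0
    cum_out = 0
    for pos in range(n):
        if in_set[pos]:
            cum_in += w[pos]
        else:
            cum_out += 1
        score += cum_in / wsum - cum_out / n_out
    return score


class TestRankGenes:
    def test_decreasing_order(self):
        order = rank_genes(np.array([5, 1, 3]))
        assert order.tolist() == [0, 2, 1]

    def test_all_zero_stable(self):
        assert rank_genes(np.zeros(5)).tolist() == [0, 1, 2, 3, 4]

    def test_seeded_random_reproducible(self):
        config = ScoringConfig(tie_policy="seeded_random", seed=42)
        a = rank_genes(np.ones(20), config)
        b = rank_genes(np.ones(20), config)
        assert a.tolist() == b.tolist()
        c = rank_genes(np.ones(20), ScoringConfig(tie_policy="seeded_random", seed=43))
        assert a.tolist() != c.tolist()

    def test_seeded_random_respects_values(self):
        config = ScoringConfig(tie_policy="seeded_random", seed=0)
        values = np.array([0, 9, 0, 9, 5])
        order = rank_genes(values, config).tolist()
        assert set(order[:2]) == {1, 3}
        assert order[2] == 4


class TestAucScore:
    UNIVERSE = [f"G{i}" for i in range(10)]

    def config(self, frac=0.5):
        return ScoringConfig(max_rank_fraction=frac)

    def test_worked_example_6_over_9(self):
        # universe 10, max_rank 5, set members at ranks 2 and 4 -> 6/9
        ranking = np.arange(10)
        gs = GeneSet("S", frozenset({"G1", "G3"}))
        score = auc_score(ranking, gs, self.UNIVERSE, self.config())
        assert score == pytest.approx(6 / 9)

    def test_maximal_recovery(self):
        ranking = np.arange(10)
        gs = GeneSet("S", frozenset({"G0", "G1"}))
        assert auc_score(ranking, gs, self.UNIVERSE, self.config()) == 1.0

    def test_no_member_in_window(self):
        ranking = np.arange(10)
        gs = GeneSet("S", frozenset({"G8", "G9"}))
        assert auc_score(ranking, gs, self.UNIVERSE, self.config()) == 0.0

    def test_disjoint_set_errors(self):
        with pytest.raises(ValidationError):
            auc_score(np.arange(10), GeneSet("S", frozenset({"ZZ"})), self.UNIVERSE, self.config())

    def test_exhaustive_oracle_small_universes(self):
        for n in (6, 9, 12):
            universe = [f"G{i}" for i in range(n)]
            config = ScoringConfig(max_rank_fraction=0.4)
            max_rank = config.max_rank(n)
            ranking = np.arange(n)
            for k in range(1, 5):
                for placement in combinations(range(n), k):
                    members = frozenset(universe[i] for i in placement)
                    gs = GeneSet("S", members)
                    assert auc_score(ranking, gs, universe, config) == pytest.approx(
                        brute_force_auc(ranking, members, universe, max_rank)
                    )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(17)
        universe = [f"G{i}" for i in range(40)]
        gs = GeneSet("S", frozenset(rng.choice(universe, size=6, replace=False)))
        config = ScoringConfig(max_rank_fraction=0.25)
        for _ in range(100):
            values = rng.integers(0, 50, size=40).astype(float)
            base = auc_score(rank_genes(values), gs, universe, config)
            for transform in (lambda x: 3 * x + 7, np.exp, lambda x: x ** 3):
                t = auc_score(rank_genes(transform(values)), gs, universe, config)
                assert t == base

    def test_boosting_member_never_decreases_score(self):
        rng = np.random.default_rng(23)
        universe = [f"G{i}" for i in range(20)]
        gs = GeneSet("S", frozenset({"G4", "G11"}))
        config = ScoringConfig(max_rank_fraction=0.3)
        for _ in range(50):
            values = rng.integers(0, 30, size=20).astype(float)
            base = auc_score(rank_genes(values), gs, universe, config)
            boosted = values.copy()
            boosted[4] += rng.integers(1, 20)
            after = auc_score(rank_genes(boosted), gs, universe, config)
            assert after >= base - 1e-12

    def test_single_member_full_window_linear_in_rank(self):
        universe = [f"G{i}" for i in range(8)]
        config = ScoringConfig(max_rank_fraction=1.0)
        n = len(universe)
        for position in range(n):
            values = np.zeros(n)
            values[position] = 1.0  # member G0 sits at rank `where G0 lands`
            gs = GeneSet("S", frozenset({universe[position]}))
            score = auc_score(rank_genes(values), gs, universe, config)
            assert score == pytest.approx(n / n)  # member at rank 1
        # sweep the member's rank explicitly via a fixed ranking
        gs = GeneSet("S", frozenset({"G0"}))
        for rank_pos in range(n):
            ranking = np.roll(np.arange(n), rank_pos)
            score = auc_score(ranking, gs, universe, config)
            assert score == pytest.approx((n - rank_pos) / n)


class TestSsgsea:
    def test_top_positions_positive_and_maximal(self):
        universe = [f"G{i}" for i in range(8)]
        gs = GeneSet("S", frozenset({"G0", "G1", "G2"}))
        top = ssgsea_score(np.array([9, 8, 7, 1, 1, 1, 1, 1.0]), gs, universe)
        assert top > 0
        rng = np.random.default_rng(3)
        for _ in range(20):
            other = ssgsea_score(rng.permutation([9, 8, 7, 1, 2, 3, 4, 5.0]), gs, universe)
            assert other <= top + 1e-12

    def test_alpha_zero_is_unweighted(self):
        universe = [f"G{i}" for i in range(8)]
        gs = GeneSet("S", frozenset({"G1", "G5"}))
        values = np.array([5, 9, 1, 2, 8, 3, 7, 4.0])
        config = ScoringConfig(ssgsea_alpha=0.0)
        score = ssgsea_score(values, gs, universe, config)
        assert score == pytest.approx(brute_force_ssgsea(values, gs.genes, universe, 0.0))

    def test_matches_brute_force_random_instances(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            n = int(rng.integers(5, 15))
            universe = [f"G{i}" for i in range(n)]
            k = int(rng.integers(1, n - 1))
            members = frozenset(rng.choice(universe, size=k, replace=False))
            values = rng.integers(0, 40, size=n).astype(float)
            alpha = float(rng.choice([0.0, 0.25, 1.0]))
            config = ScoringConfig(ssgsea_alpha=alpha)
            got = ssgsea_score(values, GeneSet("S", members), universe, config)
            want = brute_force_ssgsea(values, members, universe, alpha)
            assert got == pytest.approx(want, abs=1e-9)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(37)
        universe = [f"G{i}" for i in range(12)]
        gs = GeneSet("S", frozenset({"G2", "G5", "G9"}))
        values = rng.integers(0, 25, size=12).astype(float)
        base = ssgsea_score(values, gs, universe)
        assert ssgsea_score(values * 10 + 3, gs, universe) == pytest.approx(base)
        assert ssgsea_score(np.exp(values / 5), gs, universe) == pytest.approx(base)


class TestScoreMatrix:
    def test_duplicate_set_identical_columns(self):
        rng = np.random.default_rng(41)
        matrix = make_matrix(rng.integers(0, 20, size=(30, 8)))
        sets = [GeneSet("A", frozenset({"G1", "G5", "G9"})),
                GeneSet("B", frozenset({"G1", "G5", "G9"}))]
        table = score_matrix(matrix, sets)
        np.testing.assert_array_equal(table.column("A"), table.column("B"))

    def test_disjoint_set_missing_with_warning(self):
        matrix = make_matrix(np.ones((5, 3), dtype=int))
        sets = [GeneSet("gone", frozenset({"NOPE"}))]
        with pytest.warns(UserWarning, match="no genes found"):
            table = score_matrix(matrix, sets)
        assert np.isnan(table.column("gone")).all()
        assert "warning" in table.metadata["gone"]

    def test_low_coverage_flagged(self):
        matrix = make_matrix(np.ones((5, 2), dtype=int))
        sets = [GeneSet("half", frozenset({"G0", "MISSING"}))]
        with pytest.warns(UserWarning, match="coverage"):
            table = score_matrix(matrix, sets)
        assert table.metadata["half"]["coverage"] == 0.5

    def test_unknown_method(self):
        with pytest.raises(ConfigurationError):
            score_matrix(make_matrix(np.ones((2, 2), dtype=int)), [], method="magic")

    def test_planted_m2_high_macrophages_separate(self, study):
        from immunosite.io_formats import read_cell_table, read_gmt, read_mtx_triplet

        truth = study.ground_truth
        sets = {gs.name: gs for gs in read_gmt(study.gene_sets_path)}
        cells = read_cell_table(study.cells_path)
        scores = {}
        for sid in ("P01_tumor1", "P01_liver1"):
            d = study.sample_dirs[sid]
            matrix = read_mtx_triplet(d / "matrix.mtx", d / "features.tsv", d / "barcodes.tsv", sid)
            macro = set(cells.loc[(cells["sample_id"] == sid)
                                  & (cells["cell_type"] == "macrophage"), "barcode"])
            keep = [i for i, bc in enumerate(matrix.barcodes) if bc in macro]
            table = score_matrix(matrix.subset_cells(keep), [sets["M1"], sets["M2"]],
                                 method="ssgsea")
            scores[sid] = table
        # tumor macrophages are M2-boosted, liver macrophages M1-boosted
        tumor_m2 = np.median(scores["P01_tumor1"].column("M2"))
        tumor_m1 = np.median(scores["P01_tumor1"].column("M1"))
        liver_m2 = np.median(scores["P01_liver1"].column("M2"))
        liver_m1 = np.median(scores["P01_liver1"].column("M1"))
        assert tumor_m2 > liver_m2
        assert liver_m1 > tumor_m1
        assert tumor_m2 > tumor_m1
        assert liver_m1 > liver_m2

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 10, size=(20, 5))
        sets = [GeneSet("S", frozenset({"G2", "G7"}))]
        t1 = score_matrix(make_matrix(counts), sets)
        t2 = score_matrix(make_matrix(counts), sets)
        np.testing.assert_array_equal(t1.scores, t2.scores)
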