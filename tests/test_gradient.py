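"""Count-table reductions and color math, checked against independent
oracles (term-by-term Shannon sums, Monte-Carlo PCA optimality)."""

import math

import numpy as np
import pytest

from phylopaint import (
    CountTable,
    Gradient,
    PALETTES,
    color_at,
    parse_count_table,
    parse_mapping,
    reduce_evenness,
    reduce_mean,
    reduce_projection,
    scale_unit_interval,
    write_gradient_mapping,
)
from phylopaint.gradient import CountTableParseError


def table(rows, names=None):
    arr = np.asarray(rows, dtype=float)
    m, n = arr.shape
    names = names or [f"obs{i + 1}" for i in range(m)]
    return CountTable(names, [f"v{j + 1}" for j in range(n)], arr)


class TestParseCountTable:
    def test_shape(self):
        t = parse_count_table("id\ts1\ts2\na\t1\t2\nb\t3\t4\nc\t5\t6\n")
        assert (t.m, t.n) == (3, 2)
        assert t.observation_names == ["a", "b", "c"]
        assert t.variable_names == ["s1", "s2"]

    def test_non_numeric_cell_locates_error(self):
        with pytest.raises(CountTableParseError) as err:
            parse_count_table("id\ts1\na\t1\nb\tabc\n")
        assert err.value.row == 3 and err.value.col == 2

    def test_ragged_row_rejected(self):
        with pytest.raises(CountTableParseError):
            parse_count_table("id\ts1\ts2\na\t1\n")

    def test_negative_values_accepted(self):
        t = parse_count_table("id\ts1\na\t-2.5\n")
        assert t.values[0, 0] == -2.5

    def test_empty_input_rejected(self):
        with pytest.raises(CountTableParseError):
            parse_count_table("")


class TestMean:
    def test_arithmetic_mean(self):
        res = reduce_mean(table([[2, 4, 6]]))
        assert res.raw_scores[0] == 4.0

    def test_zero_row(self):
        assert reduce_mean(table([[0, 0, 0]])).raw_scores[0] == 0.0

    def test_single_column_identity(self):
        assert reduce_mean(table([[7.0]])).raw_scores[0] == 7.0

    def test_sum_variant(self):
        res = reduce_mean(table([[2, 4, 6]]), kind="sum")
        assert res.raw_scores[0] == 12.0


class TestEvenness:
    def test_uniform_row_is_one(self):
        assert reduce_evenness(table([[1, 1, 1, 1]])).raw_scores[0] == \
            pytest.approx(1.0)

    def test_single_support_row_is_zero(self):
        assert reduce_evenness(table([[1, 0, 0, 0]])).raw_scores[0] == \
            pytest.approx(0.0, abs=1e-12)

    def test_known_value_against_shannon_oracle(self):
        res = reduce_evenness(table([[2, 1, 1]]))
        # independent term-by-term oracle
        p = [0.5, 0.25, 0.25]
        h = -sum(pi * math.log2(pi) for pi in p)
        assert res.raw_scores[0] == pytest.approx(h / math.log2(3),
                                                  abs=1e-9)
        assert res.raw_scores[0] == pytest.approx(1.5 / math.log2(3),
                                                  abs=1e-9)

    def test_errors(self):
        with pytest.raises(ValueError):
            reduce_evenness(table([[1.0]]))  # N = 1
        with pytest.raises(ValueError, match="obs2"):
            reduce_evenness(table([[1, 1], [0, 0]]))
        with pytest.raises(ValueError):
            reduce_evenness(table([[1, -1]]))

    @pytest.mark.parametrize("seed", range(5))
    def test_scale_and_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        rows = rng.integers(0, 50, size=(200, 6)).astype(float)
        rows[rows.sum(axis=1) == 0, 0] = 1.0
        base = reduce_evenness(table(rows)).raw_scores
        scaled = reduce_evenness(table(rows * rng.uniform(0.1, 9))).raw_scores
        perm = rng.permutation(6)
        permuted = reduce_evenness(table(rows[:, perm])).raw_scores
        np.testing.assert_allclose(scaled, base, atol=1e-12)
        np.testing.assert_allclose(permuted, base, atol=1e-12)

    def test_strictly_below_one_for_non_uniform(self):
        rng = np.random.default_rng(11)
        rows = rng.integers(0, 30, size=(300, 5)).astype(float)
        rows[rows.sum(axis=1) == 0, 0] = 1.0
        uniform = np.all(rows == rows[:, :1], axis=1)
        e = reduce_evenness(table(rows)).raw_scores
        assert np.all(e[~uniform] < 1.0 - 1e-12)
        assert np.all(np.abs(e[uniform] - 1.0) < 1e-12)


class TestProjection:
    def test_collinear_rows_give_known_scores(self):
        res = reduce_projection(table([[0, 0], [2, 2], [4, 4]]))
        # oracle: covariance of centered X is [[8/3? ...]] — eigvector
        # (1,1)/sqrt(2), scores are signed distances along it
        expect = np.array([-2 * math.sqrt(2), 0.0, 2 * math.sqrt(2)])
        np.testing.assert_allclose(res.raw_scores, expect, atol=1e-9)

    def test_identical_rows_score_zero(self):
        res = reduce_projection(table([[3, 1], [3, 1], [3, 1]]))
        np.testing.assert_allclose(res.raw_scores, 0.0, atol=1e-12)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            reduce_projection(table([[1, 2]]))

    @pytest.mark.parametrize("seed", range(10))
    def test_pc1_variance_beats_random_projections(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(3, 51))
        n = int(rng.integers(2, 11))
        x = rng.normal(size=(m, n)) * rng.uniform(0.5, 3, size=n)
        res = reduce_projection(table(x))
        centered = x - x.mean(axis=0)
        dirs = rng.normal(size=(1000, n))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        proj_var = (centered @ dirs.T).var(axis=0)
        assert res.raw_scores.var() >= proj_var.max() - 1e-9

    def test_scores_sum_to_zero(self):
        rng = np.random.default_rng(5)
        res = reduce_projection(table(rng.normal(size=(20, 4))))
        assert abs(res.raw_scores.sum()) < 1e-9

    def test_sign_convention_stable_under_row_order(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(15, 4))
        res = reduce_projection(table(x))
        perm = rng.permutation(15)
        res2 = reduce_projection(table(x[perm]))
        np.testing.assert_allclose(res2.raw_scores, res.raw_scores[perm],
                                   atol=1e-9)

    def test_scaling_normalizes_column_variance(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(30, 3))
        x[:, 0] *= 100.0
        unscaled = reduce_projection(table(x), scale_variables=False)
        scaled = reduce_projection(table(x), scale_variables=True)
        # unscaled PC-1 is dominated by the inflated column
        c = x - x.mean(axis=0)
        corr = abs(np.corrcoef(unscaled.raw_scores, c[:, 0])[0, 1])
        assert corr > 0.99
        assert not np.allclose(scaled.raw_scores, unscaled.raw_scores)

    def test_zero_variance_column_tolerated_under_scaling(self):
        x = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        res = reduce_projection(table(x), scale_variables=True)
        assert np.all(np.isfinite(res.raw_scores))


class TestScaleUnitInterval:
    @pytest.mark.parametrize("scores,expect", [
        ([1, 2, 3], [0, 0.5, 1]),
        ([5], [0.5]),
        ([-2, 0, 2], [0, 0.5, 1]),
        ([7, 7, 7], [0.5, 0.5, 0.5]),
    ])
    def test_min_max(self, scores, expect):
        np.testing.assert_allclose(scale_unit_interval(scores), expect)


class TestColorAt:
    def test_cubehelix_endpoints(self):
        g = Gradient.cubehelix(start=0.5, rotations=-1.5, hue=1.0, gamma=1.0)
        assert color_at(g, 0.0) == "#000000"
        assert color_at(g, 1.0) == "#FFFFFF"
        g2 = Gradient.cubehelix(start=2.0, rotations=1.0, hue=2.0, gamma=1.0)
        assert color_at(g2, 0.0) == "#000000"
        assert color_at(g2, 1.0) == "#FFFFFF"

    def test_cubehelix_against_green_formula_oracle(self):
        s, r, h, gam = 0.5, -1.5, 1.0, 1.0
        g = Gradient.cubehelix(s, r, h, gam)
        for lam in (0.25, 0.5, 0.75):
            phi = 2 * math.pi * (s / 3 + r * lam)
            gg = lam ** gam
            a = h * gg * (1 - gg) / 2
            rgb = (gg + a * (-0.14861 * math.cos(phi)
                             + 1.78277 * math.sin(phi)),
                   gg + a * (-0.29227 * math.cos(phi)
                             - 0.90649 * math.sin(phi)),
                   gg + a * (1.97294 * math.cos(phi)))
            expect = "#%02X%02X%02X" % tuple(
                int(math.floor(min(1, max(0, v)) * 255 + 0.5)) for v in rgb)
            assert color_at(g, lam) == expect

    def test_two_stop_midpoint_rounds_half_up(self):
        g = Gradient.from_colors(["#000000", "#FF0000"])
        assert color_at(g, 0.5) == "#800000"

    def test_stops_hit_exactly(self):
        g = Gradient.from_colors(["#112233", "#445566", "#778899"])
        assert color_at(g, 0.0) == "#112233"
        assert color_at(g, 0.5) == "#445566"
        assert color_at(g, 1.0) == "#778899"

    def test_out_of_range_rejected(self):
        g = PALETTES["viridis"]
        with pytest.raises(ValueError):
            color_at(g, 1.5)

    def test_palettes_obey_stop_invariant(self):
        for name, g in PALETTES.items():
            if g.kind != "stops":
                continue
            pos = [p for p, _ in g.stops]
            assert pos[0] == 0.0 and pos[-1] == 1.0
            assert all(b > a for a, b in zip(pos, pos[1:])), name

    def test_invalid_stop_lists_rejected(self):
        with pytest.raises(ValueError):
            Gradient("stops", stops=((0.0, "#000000"),))
        with pytest.raises(ValueError):
            Gradient("stops", stops=((0.1, "#000000"), (1.0, "#FFFFFF")))

    def test_equal_scores_get_identical_colors(self):
        res = reduce_mean(table([[1, 3], [2, 2], [4, 0]]),
                          PALETTES["viridis"])
        assert res.colors[0] == res.colors[1] == res.colors[2]


class TestWriteGradientMapping:
    def test_round_trips_through_mapping_parser(self):
        t = table([[1, 1], [2, 2], [3, 3]], names=["a x", "b", "c"])
        res = reduce_mean(t, Gradient.from_colors(["#000000", "#FFFFFF"]))
        tsv = write_gradient_mapping(t, res, "branch_color")
        assert tsv.count("\n") == 4
        rules = parse_mapping(tsv)
        assert [r.pattern for r in rules] == ["a x", "b", "c"]
        assert rules[0].styles.branch_color == "#000000"
        assert rules[1].styles.branch_color == "#808080"
        assert rules[2].styles.branch_color == "#FFFFFF"

    def test_unknown_target_field_rejected(self):
        t = table([[1, 1], [2, 2]])
        res = reduce_mean(t, PALETTES["viridis"])
        with pytest.raises(ValueError):
            write_gradient_mapping(t, res, "branch_width")
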