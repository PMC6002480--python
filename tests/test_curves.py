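import numpy as np
import pytest

from treemingle.curves import (
    RGrid,
    class_mingling_curves,
    expected_mingling,
    mark_mingling_function,
    mark_product_K,
    mingling_difference,
    normalized_mingling_function,
)
from treemingle.pattern import (
    MarkedPointPattern,
    SizeClassScheme,
    TWO_CLASS_SCHEME,
    Window,
)

from oracles import brute_K_m, brute_expected_mingling, brute_k_m, random_pattern

GRID = RGrid(r_max=12.0, step=1.5)


class TestRGrid:
    def test_excludes_zero(self):
        assert GRID.r[0] == 1.5 and 0.0 not in GRID.r

    def test_strictly_increasing(self):
        assert (np.diff(GRID.r) > 0).all()

    def test_r_max_must_fit_window(self, rng):
        p = random_pattern(rng, 10, window=Window(0, 0, 20, 20))
        with pytest.raises(ValueError):
            mark_product_K(p, RGrid(r_max=25, step=1))


class TestMarkProductK:
    def test_monoculture_zero(self, monoculture):
        k = mark_product_K(monoculture, GRID)
        assert (k.values == 0).all()

    def test_two_tree_step_location(self):
        p = MarkedPointPattern(
            x=np.array([10.0, 13.0]), y=np.array([10.0, 10.0]),
            species=np.array(["A", "B"], dtype=object),
            dbh=np.array([10.0, 10.0]), window=Window(0, 0, 100, 100),
        )
        k = mark_product_K(p, RGrid(r_max=10, step=1))
        assert (k.values[:2] == 0).all()  # r = 1, 2: no pair yet
        assert k.values[2] > 0  # pair enters exactly at r = 3
        np.testing.assert_allclose(k.values[2:], k.values[2])

    def test_non_decreasing(self, rng):
        p = random_pattern(rng, 80)
        k = mark_product_K(p, GRID)
        assert (np.diff(k.values) >= 0).all()


class TestOracleAgreement:
    """Vectorised curves agree with the naive double-loop reference."""

    def test_K_and_k_whole_pattern(self, rng):
        for _ in range(8):
            n = int(rng.integers(10, 120))
            p = random_pattern(rng, n, n_species=int(rng.integers(1, 5)))
            got_K = mark_product_K(p, GRID).values
            np.testing.assert_allclose(got_K, brute_K_m(p, GRID.r), rtol=1e-12)
            got_k = mark_mingling_function(p, GRID).values
            want_k = brute_k_m(p, GRID.r)
            np.testing.assert_allclose(got_k, want_k, rtol=1e-12)

    def test_class_conditional(self, rng):
        scheme = SizeClassScheme()
        for _ in range(5):
            p = random_pattern(rng, int(rng.integers(30, 100)))
            for label in scheme.labels:
                mask = scheme.class_mask(p, label)
                if not mask.any():
                    continue
                got = mark_mingling_function(p, GRID, scheme, label).values
                want = brute_k_m(p, GRID.r, mask)
                np.testing.assert_allclose(got, want, rtol=1e-12)

    def test_multi_class_helper_matches_single(self, rng):
        scheme = SizeClassScheme()
        p = random_pattern(rng, 90)
        multi = class_mingling_curves(p, GRID, scheme)
        for label in scheme.labels:
            if scheme.class_mask(p, label).any():
                single = mark_mingling_function(p, GRID, scheme, label).values
                np.testing.assert_allclose(multi[label], single, rtol=1e-12)

    def test_unordered_pair_doubling_identity(self, rng):
        """Whole-pattern sums over ordered pairs equal doubled sums over
        unordered pairs (each pair contributes twice with equal weight)."""
        import math

        from treemingle.curves import _pair_cumsums
        from treemingle.pattern import translation_weight

        p = random_pattern(rng, 50)
        num, den = _pair_cumsums(p, GRID)
        num2 = np.zeros(GRID.r.size)
        den2 = np.zeros(GRID.r.size)
        for i in range(p.n):
            for j in range(i + 1, p.n):
                d = math.hypot(p.x[i] - p.x[j], p.y[i] - p.y[j])
                w = translation_weight(p.window, p.x[i] - p.x[j], p.y[i] - p.y[j])
                het = float(p.species[i] != p.species[j])
                sel = GRID.r >= d
                num2[sel] += 2 * het * w
                den2[sel] += 2 * w
        np.testing.assert_allclose(num, num2, rtol=1e-12)
        np.testing.assert_allclose(den, den2, rtol=1e-12)


class TestMarkMinglingFunction:
    def test_hand_computed_four_trees(self, four_tree_pattern):
        grid = RGrid(r_max=2.0, step=2.0)
        k = mark_mingling_function(four_tree_pattern, grid)
        w1 = 400 / (19 * 20)  # |dx| = 1 or |dy| = 1
        w2 = 400 / (19 * 19)  # |dx| = |dy| = 1
        want = (2 * (w1 + w2)) / (2 * (w1 + w1 + w2))
        assert k.values[0] == pytest.approx(want, rel=1e-12)
        assert k.values[0] == pytest.approx(0.6724, abs=5e-5)

    def test_monoculture_zero_where_defined(self, monoculture):
        k = mark_mingling_function(monoculture, GRID)
        defined = ~np.isnan(k.values)
        assert (k.values[defined] == 0).all()

    def test_undefined_marked_nan_not_zero(self):
        # two far-apart trees: no pair within short r
        p = MarkedPointPattern(
            x=np.array([5.0, 95.0]), y=np.array([5.0, 95.0]),
            species=np.array(["A", "B"], dtype=object),
            dbh=np.array([10.0, 10.0]), window=Window(0, 0, 100, 100),
        )
        k = mark_mingling_function(p, RGrid(r_max=10, step=1))
        assert np.isnan(k.values).all()

    def test_values_in_unit_interval(self, rng):
        p = random_pattern(rng, 150, n_species=4)
        k = mark_mingling_function(p, GRID).values
        defined = ~np.isnan(k)
        assert ((k[defined] >= 0) & (k[defined] <= 1)).all()

    def test_empty_reference_class_rejected(self, monoculture):
        scheme = SizeClassScheme()
        # monoculture fixture has dbh in [6, 40]; force an empty class
        p = MarkedPointPattern(
            x=monoculture.x, y=monoculture.y, species=monoculture.species,
            dbh=np.full(monoculture.n, 7.0), window=monoculture.window,
        )
        with pytest.raises(ValueError, match="empty"):
            mark_mingling_function(p, GRID, scheme, "large")


class TestExpectedMingling:
    def test_monoculture_zero(self, monoculture):
        scheme = SizeClassScheme()
        assert expected_mingling(monoculture, scheme, "medium") == 0

    def test_hand_value_partial_class(self):
        # n = 10: species A x 6, B x 4; "large" class holds 2 A + 3 B
        # A-large: ids 0, 1; B-large: ids 6, 7, 8 -> n_d = 5, n_dA = 2, n_dB = 3
        sp = np.array(["A", "A", "A", "A", "A", "A", "B", "B", "B", "B"], dtype=object)
        dbh = np.array([30, 30, 8, 8, 8, 8, 30, 30, 30, 8], dtype=float)
        rng = np.random.default_rng(3)
        p = MarkedPointPattern(
            x=rng.uniform(0, 100, 10), y=rng.uniform(0, 100, 10),
            species=sp, dbh=dbh, window=Window(0, 0, 100, 100),
        )
        em = expected_mingling(p, SizeClassScheme(), "large")
        assert em == pytest.approx(26 / 45, rel=1e-12)
        assert em == pytest.approx(brute_expected_mingling(p, dbh > 25), rel=1e-12)

    def test_hand_value_whole_pattern_class(self):
        # all 10 trees in one class, two species 5/5 -> 5/9
        sp = np.array(["A"] * 5 + ["B"] * 5, dtype=object)
        rng = np.random.default_rng(4)
        p = MarkedPointPattern(
            x=rng.uniform(0, 100, 10), y=rng.uniform(0, 100, 10),
            species=sp, dbh=np.full(10, 15.0), window=Window(0, 0, 100, 100),
        )
        em = expected_mingling(p, SizeClassScheme(), "medium")
        assert em == pytest.approx(5 / 9, rel=1e-12)

    def test_matches_brute_force(self, rng):
        scheme = SizeClassScheme()
        for _ in range(10):
            p = random_pattern(rng, int(rng.integers(20, 80)))
            for label in scheme.labels:
                mask = scheme.class_mask(p, label)
                if mask.any():
                    assert expected_mingling(p, scheme, label) == pytest.approx(
                        brute_expected_mingling(p, mask), rel=1e-12
                    )


class TestNormalizedAndDifference:
    def test_normalized_is_ratio(self, rng):
        scheme = SizeClassScheme()
        p = random_pattern(rng, 100)
        base = mark_mingling_function(p, GRID, scheme, "medium").values
        norm = normalized_mingling_function(p, GRID, scheme, "medium")
        np.testing.assert_allclose(norm.values, base / norm.em_d, rtol=1e-12)

    def test_monospecific_normalization_error(self, monoculture):
        with pytest.raises(ZeroDivisionError):
            normalized_mingling_function(
                monoculture, GRID, SizeClassScheme(), "medium"
            )

    def test_difference_same_class_zero(self, rng):
        scheme = SizeClassScheme()
        p = random_pattern(rng, 100)
        d = mingling_difference(p, GRID, scheme, "large", "large")
        defined = ~np.isnan(d.values)
        assert (d.values[defined] == 0).all()

    def test_difference_antisymmetric(self, rng):
        scheme = SizeClassScheme()
        p = random_pattern(rng, 100)
        ab = mingling_difference(p, GRID, scheme, "large", "small").values
        ba = mingling_difference(p, GRID, scheme, "small", "large").values
        np.testing.assert_allclose(ab, -ba, rtol=1e-12)

    def test_difference_in_band(self, rng):
        scheme = SizeClassScheme()
        p = random_pattern(rng, 150)
        d = mingling_difference(p, GRID, scheme, "large", "small").values
        defined = ~np.isnan(d)
        assert ((d[defined] >= -1) & (d[defined] <= 1)).all()


class TestRandomLabellingBehaviour:
    def test_whole_pattern_curve_approaches_expected_mingling(self, rng):
        """At r near r_max (nearly all pairs) the whole-pattern curve under
        random labelling matches the random-arrangement expectation."""
        base = random_pattern(rng, 100, n_species=1)
        labels = np.array(
            ["A"] * 40 + ["B"] * 35 + ["C"] * 25, dtype=object
        )
        n = 100
        expect = sum(
            c * (n - c) / (n * (n - 1)) for c in (40, 35, 25)
        )
        grid = RGrid(r_max=90, step=90)
        vals = []
        for _ in range(60):
            p = MarkedPointPattern(
                x=base.x, y=base.y, species=labels[rng.permutation(n)],
                dbh=base.dbh, window=base.window,
            )
            vals.append(mark_mingling_function(p, grid).values[-1])
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - expect) < 3 * se

    def test_normalized_fluctuates_about_one(self, rng):
        scheme = SizeClassScheme()
        base = random_pattern(rng, 120, n_species=1)
        labels = np.array(["A"] * 50 + ["B"] * 40 + ["C"] * 30, dtype=object)
        grid = RGrid(r_max=20, step=2.5)
        grand = []
        for _ in range(60):
            p = MarkedPointPattern(
                x=base.x, y=base.y, species=labels[rng.permutation(120)],
                dbh=base.dbh, window=base.window,
            )
            v = normalized_mingling_function(p, grid, scheme, "medium").values
            grand.append(np.nanmean(v))
        se = np.std(grand, ddof=1) / np.sqrt(len(grand))
        assert abs(np.mean(grand) - 1) < 3 * se

    def test_normalized_no_trend_in_r(self, rng):
        """Slope of the mean normalised curve over r is ~0 under random
        labelling."""
        scheme = SizeClassScheme()
        base = random_pattern(rng, 120, n_species=1)
        labels = np.array(["A"] * 60 + ["B"] * 60, dtype=object)
        grid = RGrid(r_max=20, step=2.5)
        curves = []
        for _ in range(80):
            p = MarkedPointPattern(
                x=base.x, y=base.y, species=labels[rng.permutation(120)],
                dbh=base.dbh, window=base.window,
            )
            curves.append(
                normalized_mingling_function(p, grid, scheme, "medium").values
            )
        curves = np.array(curves)
        slopes = [
            np.polyfit(grid.r, c, 1)[0] for c in curves if not np.isnan(c).any()
        ]
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes)) < 3 * se
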