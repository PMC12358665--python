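"""The descriptor-selection cascade and its stages."""

import copy

import numpy as np
import pytest
from scipy import stats

from skinqsar import select, synthdata
from skinqsar.featurize import DescriptorBlock, EmptyFeatureError


def _block(values, names=None):
    values = np.asarray(values, dtype=float)
    names = names or [f"d{i}" for i in range(values.shape[1])]
    return DescriptorBlock(values, names,
                           [f"r{i}" for i in range(values.shape[0])])


class TestVarianceFilter:
    def test_hand_computed_variances(self, rng):
        # two rows: sample variance per column is diff^2 / 2, so the
        # columns have variances {0, 0.5, 2, 1e-9} exactly
        block = _block(np.array([
            [1.0, 0.0, 0.0, 0.0],
            [1.0, 1.0, 2.0, np.sqrt(2e-9)],
        ]))
        v = block.values.var(axis=0, ddof=1)
        assert v[0] == 0 and v[1] == pytest.approx(0.5) \
            and v[2] == pytest.approx(2.0) and v[3] == pytest.approx(1e-9)
        kept = select.low_variance_filter(block, threshold=1e-8)
        assert kept.names == ["d1", "d2"]

    def test_constant_column_removed(self):
        block = _block([[1, 2, 3], [1, 5, 4], [1, 8, 5]])
        assert select.low_variance_filter(block).names == ["d1", "d2"]

    def test_threshold_zero_no_constant_is_identity(self):
        block = _block([[1, 2], [3, 4], [5, 7]])
        assert select.low_variance_filter(block, 0.0).names == ["d0", "d1"]

    def test_all_removed_is_error(self):
        block = _block([[1, 1], [1, 1]])
        with pytest.raises(EmptyFeatureError):
            select.low_variance_filter(block)


class TestStandardize:
    def test_sample_sd_convention(self):
        out, means, sds = select.standardize(_block([[1], [2], [3]]))
        assert means[0] == 2 and sds[0] == pytest.approx(1.0)   # ddof=1
        assert out.values.ravel() == pytest.approx([-1, 0, 1])

    def test_self_transform_centers(self, rng):
        block = _block(rng.normal(3, 2, (50, 4)))
        out, means, sds = select.standardize(block)
        again = select.standardize(block, means, sds)
        assert np.allclose(again.values.mean(axis=0), 0, atol=1e-12)

    def test_shifted_copy_closed_form(self, rng):
        block = _block(rng.normal(0, 1, (30, 3)))
        _, means, sds = select.standardize(block)
        shifted = _block(block.values + 10)
        out = select.standardize(shifted, means, sds)
        assert np.allclose(out.values.mean(axis=0), 10 / sds, atol=1e-9)


class TestAnova:
    def test_hand_computed_f_ratio(self):
        """Groups {1,2,3} and {6,7,8}: between/within mean squares give F=37.5."""
        g0, g1 = [1.0, 2.0, 3.0], [6.0, 7.0, 8.0]
        F, p = stats.f_oneway(g0, g1)
        assert F == pytest.approx(37.5)
        block = _block(np.array(g0 + g1).reshape(-1, 1))
        kept = select.anova_screen(block, [0, 0, 0, 1, 1, 1], alpha=0.05)
        assert kept == ["d0"]

    def test_identical_distribution_column_removed(self, rng):
        y = np.repeat([0, 1], 30)
        same = rng.normal(0, 1, 60)
        sep = y + rng.normal(0, 0.01, 60)
        block = _block(np.column_stack([same, sep]), ["flat", "sep"])
        assert select.anova_screen(block, y) == ["sep"]

    def test_tiny_class_is_error(self):
        block = _block([[1.0], [2.0], [3.0]])
        with pytest.raises(ValueError):
            select.anova_screen(block, [0, 0, 1])


class TestL1:
    def test_soft_threshold_closed_form(self, rng):
        """Single standardized feature: Lasso coefficient equals
        max(0, cov - lam) / var in the orthonormal-design closed form."""
        n = 200
        x = rng.normal(0, 1, n)
        x = (x - x.mean())
        y = (x + rng.normal(0, 0.5, n) > 0).astype(int)
        yc = y - y.mean()
        lam = 0.05
        cov = float(x @ yc) / n
        var = float(x @ x) / n
        expected = np.sign(cov) * max(0.0, abs(cov) - lam) / var
        kept, _ = select.l1_select(_block(x.reshape(-1, 1)), y, strength=lam)
        from sklearn.linear_model import Lasso
        coef = Lasso(alpha=lam).fit(x.reshape(-1, 1), y).coef_[0]
        assert coef == pytest.approx(expected, abs=1e-6)
        assert kept == (["d0"] if expected != 0 else [])

    def test_infinite_strength_empties_selection(self, rng):
        block = _block(rng.normal(0, 1, (40, 3)))
        y = rng.integers(0, 2, 40)
        with pytest.raises(EmptyFeatureError):
            select.l1_select(block, y, strength=1e6)

    def test_zero_strength_keeps_full_rank_columns(self, rng):
        block = _block(rng.normal(0, 1, (50, 4)))
        y = rng.integers(0, 2, 50)
        kept, _ = select.l1_select(block, y, strength=0.0)
        assert kept == block.names


class TestCascade:
    def test_nesting_and_apply_reproducibility(self, rng):
        block, y, _ = synthdata.make_informative_descriptors(
            n=200, n_informative=4, n_noise=16, seed=1)
        cascade = select.DescriptorSelectionCascade(l1_strength=0.02)
        cascade.fit(block, y)
        st = cascade.state_
        assert set(st.l1_kept) <= set(st.anova_kept) \
            <= set(st.retained_after_variance)
        out = cascade.transform(block)
        assert out.names == st.l1_kept

    def test_apply_never_refits(self, rng):
        block, y, _ = synthdata.make_informative_descriptors(n=120, seed=2)
        cascade = select.DescriptorSelectionCascade(l1_strength=0.05).fit(block, y)
        before = copy.deepcopy(cascade.state_)
        other, _, _ = synthdata.make_informative_descriptors(n=60, seed=3)
        cascade.transform(other)
        after = cascade.state_
        assert before.l1_kept == after.l1_kept
        assert np.array_equal(before.means, after.means)

    def test_support_recovery_on_planted_signal(self):
        """>= 4 of 5 planted informative descriptors survive; recall >= 0.8."""
        block, y, informative = synthdata.make_informative_descriptors(
            n=500, n_informative=5, n_noise=45, effect=1.0, seed=7)
        state = select.fit_cascade(block, y, l1_strength="cv", random_state=7)
        recovered = set(state.l1_kept) & set(informative)
        assert len(recovered) >= 4

    def test_deterministic_under_fixed_settings(self):
        block, y, _ = synthdata.make_informative_descriptors(n=150, seed=4)
        s1 = select.fit_cascade(block, y, l1_strength="cv", random_state=9)
        s2 = select.fit_cascade(block, y, l1_strength="cv", random_state=9)
        assert s1.l1_kept == s2.l1_kept and s1.l1_strength == s2.l1_strength
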