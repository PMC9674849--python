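"""Mass-univariate t-maps and Benjamini-Hochberg FDR thresholding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from bodymaps import build_default_template, fdr_threshold, group_maps_for_cohort, pixelwise_ttest
from bodymaps.preprocess import SubjectBSM, build_cohort_bsms
from bodymaps.simulate import CohortConfig, TopographyComponent, TopographySpec, simulate_cohort


def bh_bruteforce(p, alpha):
    """Independent BH oracle: sort, scan every k, keep largest passing k."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.sort(p)
    crit, found = 0.0, False
    for k in range(1, m + 1):
        if order[k - 1] <= k * alpha / m:
            crit, found = order[k - 1], True
    return crit, p <= crit if found else np.zeros(m, bool)


def constant_stack(template, values):
    """One BSM per subject, each constant over the mask."""
    stack = []
    for i, v in enumerate(values):
        grid = template.zeros()
        grid[template.mask] = v
        stack.append(SubjectBSM(f"S{i}", "x", grid))
    return stack


class TestPixelwiseTtest:
    def test_textbook_example(self, small_template):
        """Samples (1,2,3) give t = mean/(sd/sqrt(n)) = 3.4641 with df=2
        and two-sided p = 0.0742."""
        gm = pixelwise_ttest(constant_stack(small_template, [1, 2, 3]), small_template)
        t_in = gm.t[small_template.mask]
        p_in = gm.p[small_template.mask]
        assert np.allclose(t_in, 3.4641, atol=1e-4)
        assert np.allclose(p_in, 0.0742, atol=1e-3)
        assert gm.df == 2

    def test_sign_antisymmetry(self, small_template):
        gm_pos = pixelwise_ttest(constant_stack(small_template, [1, 2, 3]), small_template)
        gm_neg = pixelwise_ttest(constant_stack(small_template, [-1, -2, -3]), small_template)
        assert np.allclose(gm_neg.t, -gm_pos.t)
        assert np.allclose(gm_neg.p, gm_pos.p)

    def test_all_zero_pixels_get_t0_p1(self, small_template):
        gm = pixelwise_ttest(constant_stack(small_template, [0, 0, 0]), small_template)
        assert (gm.t[small_template.mask] == 0).all()
        assert (gm.p[small_template.mask] == 1).all()

    def test_zero_variance_nonzero_mean_sentinel(self, small_template):
        gm = pixelwise_ttest(constant_stack(small_template, [2, 2, 2]), small_template)
        assert np.isposinf(gm.t[small_template.mask]).all()
        assert (gm.p[small_template.mask] == 0).all()

    def test_matches_scipy_oracle_on_random_stacks(self, rng):
        t = build_default_template(40, 80)
        for n in (3, 5, 12):
            arr = rng.normal(0.2, 1.0, size=(n, t.height, t.width))
            arr[:, ~t.mask] = 0.0
            gm = pixelwise_ttest(arr, t)
            X = arr[:, t.mask]
            res = sps.ttest_1samp(X, 0.0, axis=0)
            assert np.allclose(gm.t[t.mask], res.statistic, atol=1e-10)
            assert np.allclose(gm.p[t.mask], res.pvalue, atol=1e-10)

    def test_fewer_than_two_subjects_rejected(self, small_template):
        with pytest.raises(ValueError):
            pixelwise_ttest(constant_stack(small_template, [1.0]), small_template)


class TestFdrThreshold:
    def test_step_up_keeps_all_when_largest_p_passes(self):
        """p = {.005,.01,.03,.04} at alpha .05, m=4: BH thresholds are
        .0125/.025/.0375/.05 and the largest p passes its own, so all 4
        are significant."""
        crit, sig = fdr_threshold(np.array([0.005, 0.01, 0.03, 0.04]), alpha=0.05)
        assert crit == pytest.approx(0.04)
        assert sig.all()

    def test_none_significant(self):
        crit, sig = fdr_threshold(np.array([0.04, 0.5, 0.9]), alpha=0.05)
        assert crit == 0.0
        assert not sig.any()

    def test_all_ones_empty_mask(self):
        crit, sig = fdr_threshold(np.ones(50), alpha=0.05)
        assert crit == 0.0 and not sig.any()

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 400),
           st.sampled_from([0.01, 0.05, 0.1]))
    def test_matches_bruteforce_oracle(self, seed, m, alpha):
        r = np.random.default_rng(seed)
        # mix of null and signal p-values, with ties
        p = np.round(r.beta(0.5, 3.0, size=m), 3)
        crit, sig = fdr_threshold(p, alpha=alpha)
        crit_o, sig_o = bh_bruteforce(p, alpha)
        assert crit == pytest.approx(crit_o, abs=1e-12)
        assert np.array_equal(sig, sig_o)

    def test_monotone_in_alpha(self, rng):
        p = rng.uniform(size=300)
        prev = np.zeros(300, bool)
        for alpha in (0.01, 0.05, 0.1, 0.2):
            _, sig = fdr_threshold(p, alpha=alpha)
            assert (prev <= sig).all()  # enlarging alpha never shrinks the mask
            prev = sig

    def test_grid_mode_restricts_to_mask(self, small_template):
        p = np.ones(small_template.mask.shape)
        p[small_template.mask] = 1e-6
        crit, sig = fdr_threshold(p, alpha=0.05, template=small_template)
        assert sig.sum() == small_template.n_in_mask
        assert not sig[~small_template.mask].any()


@pytest.fixture(scope="module")
def maps_and_cohort():
    template = build_default_template(60, 120)
    specs = [
        TopographySpec("left", (TopographyComponent("head", 1, 2.0),)),
        TopographySpec("right", (TopographyComponent("head", 1, 2.0),)),
    ]
    config = CohortConfig(
        n_subjects=50, stimuli=("left", "right"), subject_noise_sd=1.0,
        paint_threshold=1.0, brush_radius=2, completion_prob=1.0, seed=77,
    )
    cohort = simulate_cohort(template, specs, config)
    bsms = build_cohort_bsms(cohort, template, 2, 1.0)
    maps = group_maps_for_cohort(bsms, template, stimuli=["left", "right"])
    return template, cohort, maps


class TestGroupMapsForCohort:

    def test_identical_specs_give_overlapping_sig_masks(self, maps_and_cohort):
        template, _, maps = maps_and_cohort
        a, b = (gm.sig_mask & (gm.t > 0) for gm in maps)
        jaccard = (a & b).sum() / (a | b).sum()
        assert jaccard >= 0.6

    def test_every_sig_pixel_beats_the_critical_p(self, maps_and_cohort):
        template, _, maps = maps_and_cohort
        for gm in maps:
            assert not gm.sig_mask[~template.mask].any()
            assert (gm.p[gm.sig_mask] <= gm.fdr_critical_p).all()

    def test_min_sig_abs_t_separates_sig_from_nonsig(self, maps_and_cohort):
        """min_sig_abs_t is the display threshold: every significant
        pixel is at or above it, every non-significant in-mask pixel is
        below it or has p above the critical p."""
        template, _, maps = maps_and_cohort
        for gm in maps:
            assert np.abs(gm.t[gm.sig_mask]).min() == gm.min_sig_abs_t
            nonsig = template.mask & ~gm.sig_mask
            ok = (np.abs(gm.t[nonsig]) < gm.min_sig_abs_t) | (gm.p[nonsig] > gm.fdr_critical_p)
            assert ok.all()

    def test_pooled_fdr_shares_one_critical_p(self, maps_and_cohort):
        template, cohort, _ = maps_and_cohort
        bsms = build_cohort_bsms(cohort, template, 2, 1.0)
        pooled = group_maps_for_cohort(bsms, template, stimuli=["left", "right"], pooled_fdr=True)
        assert pooled[0].fdr_critical_p == pooled[1].fdr_critical_p

    def test_understaffed_stimulus_rejected(self, small_template):
        grid = small_template.zeros()
        bsms = [SubjectBSM("S1", "only", grid)]
        with pytest.raises(ValueError):
            group_maps_for_cohort(bsms, small_template)
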