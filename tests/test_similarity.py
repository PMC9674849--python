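"""Spearman similarity between maps, within and across studies."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import pearsonr

from bodymaps import (
    BodyTemplate,
    cross_study_similarity,
    similarity_matrix,
    spearman_similarity,
)
from bodymaps.stats import GroupMap


def average_ranks(v):
    """Independent ranking oracle: sort-based average ranks for ties."""
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v), float)
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def tiny_template(n=4):
    mask = np.zeros((2, max(n, 2)), bool)
    mask[0, :n] = True
    return BodyTemplate(width=mask.shape[1], height=2, mask=mask)


def as_grid(template, vec):
    grid = template.zeros()
    grid[template.mask] = vec
    return grid


def group_map(template, grid, stimulus):
    return GroupMap(
        stimulus=stimulus, n_subjects=10, t=grid, p=np.ones_like(grid), alpha=0.05,
        fdr_critical_p=0.0, sig_mask=np.zeros_like(grid, bool), min_sig_abs_t=float("nan"),
    )


class TestSpearman:
    def test_self_similarity_is_one(self, small_template, rng):
        grid = rng.normal(size=small_template.mask.shape)
        assert spearman_similarity(grid, grid, small_template) == pytest.approx(1.0)

    def test_negation_gives_minus_one(self, small_template, rng):
        grid = rng.normal(size=small_template.mask.shape)
        assert spearman_similarity(grid, -grid, small_template) == pytest.approx(-1.0)

    def test_single_swap_example(self):
        """(1,2,3,4) vs (1,3,2,4): sum d^2 = 2, rho = 1 - 6*2/(4*15) = 0.8."""
        t = tiny_template(4)
        r = spearman_similarity(as_grid(t, [1, 2, 3, 4]), as_grid(t, [1, 3, 2, 4]), t)
        assert r == pytest.approx(0.8)

    def test_constant_map_is_undefined(self, small_template, rng):
        grid = rng.normal(size=small_template.mask.shape)
        assert np.isnan(spearman_similarity(np.zeros_like(grid), grid, small_template))

    def test_template_mismatch_rejected(self, small_template):
        with pytest.raises(ValueError):
            spearman_similarity(np.zeros((3, 3)), np.zeros((3, 3)), small_template)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(5, 200))
    def test_matches_rank_then_pearson_oracle(self, seed, n):
        """Implementation equals average-rank-then-Pearson, including ties."""
        r = np.random.default_rng(seed)
        t = tiny_template(n)
        a = np.round(r.normal(size=n), 1)  # rounding forces ties
        b = np.round(r.normal(size=n), 1)
        got = spearman_similarity(as_grid(t, a), as_grid(t, b), t)
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            assert np.isnan(got)
        else:
            expected = pearsonr(average_ranks(a), average_ranks(b)).statistic
            assert got == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        r = np.random.default_rng(seed)
        t = tiny_template(50)
        a, b = r.normal(size=50), r.normal(size=50)
        base = spearman_similarity(as_grid(t, a), as_grid(t, b), t)
        warped = spearman_similarity(as_grid(t, np.exp(3 * a) + 7), as_grid(t, b), t)
        assert warped == pytest.approx(base, abs=1e-12)


class TestSimilarityMatrix:
    def test_identical_maps_all_ones(self, small_template, rng):
        grid = rng.normal(size=small_template.mask.shape)
        maps = [group_map(small_template, grid.copy(), f"s{i}") for i in range(3)]
        sim = similarity_matrix(maps, small_template)
        assert np.allclose(sim.r, 1.0)
        assert sim.n_pixels_used == small_template.n_in_mask

    def test_symmetric_unit_diagonal_bounded(self, small_template, rng):
        maps = [
            group_map(small_template, rng.normal(size=small_template.mask.shape), f"s{i}")
            for i in range(5)
        ]
        sim = similarity_matrix(maps, small_template)
        assert np.allclose(sim.r, sim.r.T)
        assert np.allclose(np.diag(sim.r), 1.0)
        assert (np.abs(sim.r) <= 1.0).all()

    def test_permutation_equivariance(self, small_template, rng):
        maps = [
            group_map(small_template, rng.normal(size=small_template.mask.shape), f"s{i}")
            for i in range(4)
        ]
        sim = similarity_matrix(maps, small_template)
        perm = [2, 0, 3, 1]
        sim_p = similarity_matrix([maps[i] for i in perm], small_template)
        assert sim_p.labels == [f"s{i}" for i in perm]
        assert np.allclose(sim_p.r, sim.r[np.ix_(perm, perm)])

    def test_constant_map_yields_nan_entries_and_warns(self, small_template, rng):
        maps = [
            group_map(small_template, rng.normal(size=small_template.mask.shape), "a"),
            group_map(small_template, small_template.zeros(), "flat"),
        ]
        with pytest.warns(UserWarning, match="flat"):
            sim = similarity_matrix(maps, small_template)
        assert np.isnan(sim.r[0, 1]) and np.isnan(sim.r[1, 0])
        assert sim.r[1, 1] == 1.0


class TestCrossStudy:
    def test_reference_copy_gives_unit_coefficients(self, small_template, rng):
        maps = [
            group_map(small_template, rng.normal(size=small_template.mask.shape), s)
            for s in ("fear", "anger")
        ]
        ref = {"Fear": maps[0].t.copy(), "ANGER": maps[1].t.copy()}  # case-insensitive
        out = cross_study_similarity(maps, ref, small_template)
        assert out == {"fear": pytest.approx(1.0), "anger": pytest.approx(1.0)}

    def test_noisy_reference_stays_highly_similar(self, small_template, rng):
        maps = [
            group_map(small_template, rng.uniform(-1, 1, size=small_template.mask.shape), s)
            for s in ("fear", "anger", "love")
        ]
        ref = {}
        for gm in maps:
            span = np.ptp(gm.t[small_template.mask])
            ref[gm.stimulus] = gm.t + rng.normal(0, 0.1 * span, size=gm.t.shape)
        out = cross_study_similarity(maps, ref, small_template)
        assert all(r > 0.9 for r in out.values())

    def test_reference_on_other_canvas_is_resampled(self, small_template, rng):
        grid = rng.normal(size=small_template.mask.shape)
        maps = [group_map(small_template, grid, "fear")]
        big = np.kron(grid, np.ones((2, 2)))  # same map at twice the resolution
        out = cross_study_similarity(maps, {"fear": big}, small_template)
        assert out["fear"] == pytest.approx(1.0)

    def test_disjoint_labels_rejected(self, small_template, rng):
        maps = [group_map(small_template, rng.normal(size=small_template.mask.shape), "fear")]
        with pytest.raises(ValueError):
            cross_study_similarity(maps, {"anger": maps[0].t}, small_template)
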