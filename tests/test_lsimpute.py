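"""Li-Stephens forward-backward, imputation and the estimated-r^2 score."""

import numpy as np
import pytest

from imputebench import LSParams, estimated_r2, impute, ls_forward_backward
from imputebench.lsimpute import _switch_probs
from imputebench.synthpop import HaplotypePanel

from .conftest import make_panel
from .oracles import ls_posteriors_by_enumeration


class TestForwardBackward:
    @pytest.mark.parametrize("n_haps,n_sites,seed", [(2, 3, 0), (3, 4, 1), (3, 4, 2), (2, 4, 3)])
    def test_matches_path_enumeration(self, n_haps, n_sites, seed):
        rng = np.random.default_rng(seed)
        ref = rng.integers(0, 2, size=(n_haps, n_sites)).astype(np.int8)
        obs = rng.integers(0, 2, size=n_sites).astype(np.int8)
        params = LSParams(n_eff=100.0, err=0.05)
        pos = np.cumsum(rng.uniform(0.001, 0.01, n_sites))
        rho = _switch_probs(pos, n_haps, params)
        got = ls_forward_backward(obs, ref, params, pos_morgans=pos)
        want = ls_posteriors_by_enumeration(obs, ref, rho, params.err)
        assert np.max(np.abs(got - want)) < 1e-10

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(5)
        ref = rng.integers(0, 2, size=(8, 30)).astype(np.int8)
        obs = rng.integers(0, 2, size=30).astype(np.int8)
        post = ls_forward_backward(obs, ref, LSParams())
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_perfect_copy_concentrates_posterior(self):
        rng = np.random.default_rng(6)
        ref = rng.integers(0, 2, size=(5, 40)).astype(np.int8)
        pos = np.arange(40) * 1e-5  # tightly linked sites
        post = ls_forward_backward(ref[2], ref, LSParams(n_eff=100, err=1e-8), pos_morgans=pos)
        assert (post[:, 2] >= 0.999).all()

    def test_uniform_panel_gives_uniform_posterior(self):
        ref = np.tile(np.array([0, 1, 1, 0, 1], dtype=np.int8), (4, 1))
        obs = ref[0]
        post = ls_forward_backward(obs, ref, LSParams())
        np.testing.assert_allclose(post, 0.25, atol=1e-12)

    def test_no_reference_haplotypes_raises(self):
        with pytest.raises(ValueError):
            ls_forward_backward(np.array([0, 1]), np.empty((0, 2), dtype=np.int8), LSParams())


def _panel_from(haps, pos=None):
    return make_panel(np.asarray(haps, dtype=np.int8), pos=pos)


class TestImpute:
    def test_perfect_panel_recovery(self):
        """Targets copied from the panel are recovered at the untyped sites."""
        rng = np.random.default_rng(7)
        n_sites = 60
        ref_haps = rng.integers(0, 2, size=(40, n_sites)).astype(np.int8)
        ref = _panel_from(ref_haps)
        # targets: copies of reference haplotypes, typed at every 4th site
        tgt_haps = ref_haps[:10]
        typed_idx = np.arange(0, n_sites, 4)
        targets = _panel_from(tgt_haps).subset_sites(typed_idx)
        dos, log = impute(targets, ref, LSParams(err=1e-8))
        assert log.typed_sites_absent_from_ref == 0
        untyped = ~dos.typed
        assert np.array_equal(np.round(dos.hds[:, untyped]), tgt_haps[:, untyped])

    def test_two_haplotype_closed_form(self):
        """H=2, one typed site: posterior and dosages in closed form."""
        ref_haps = np.array([[1, 1, 1], [0, 0, 0]], dtype=np.int8)
        ref = _panel_from(ref_haps, pos=[100, 200, 300])
        targets = _panel_from(np.array([[1], [0]], dtype=np.int8), pos=[200])
        err = 1e-3
        dos, _ = impute(targets, ref, LSParams(err=err))
        # with a single typed site the posterior is emission-only:
        # P(copy h1 | obs=1) = (1-err) / 1 -> hds at untyped sites = 1-err
        p1 = (1 - err) / ((1 - err) + err)
        np.testing.assert_allclose(dos.hds[0], [p1, p1, p1], atol=1e-9)
        np.testing.assert_allclose(dos.hds[1], [1 - p1, 1 - p1, 1 - p1], atol=1e-9)

    def test_restriction_consistency(self):
        """Typed sites absent from the reference are dropped, not disruptive."""
        rng = np.random.default_rng(8)
        ref_haps = rng.integers(0, 2, size=(30, 50)).astype(np.int8)
        ref = _panel_from(ref_haps)
        tgt_haps = ref_haps[:6]
        typed_idx = np.arange(0, 50, 5)
        targets_full = _panel_from(tgt_haps).subset_sites(typed_idx)
        # reference missing two of the typed sites
        keep = np.setdiff1d(np.arange(50), typed_idx[[2, 5]])
        ref_missing = ref.subset_sites(keep)
        dos_a, log = impute(targets_full, ref_missing, LSParams())
        assert log.typed_sites_absent_from_ref == 2
        targets_pre = _panel_from(tgt_haps).subset_sites(np.setdiff1d(typed_idx, typed_idx[[2, 5]]))
        dos_b, _ = impute(targets_pre, ref_missing, LSParams())
        np.testing.assert_allclose(dos_a.hds, dos_b.hds, atol=1e-12)

    def test_no_overlap_raises(self):
        ref = _panel_from(np.zeros((4, 3), dtype=np.int8), pos=[10, 20, 30])
        targets = _panel_from(np.zeros((2, 2), dtype=np.int8), pos=[15, 25])
        with pytest.raises(ValueError, match="overlap"):
            impute(targets, ref, LSParams())

    def test_loo_defined_exactly_at_typed_sites(self):
        rng = np.random.default_rng(9)
        ref = _panel_from(rng.integers(0, 2, size=(20, 30)).astype(np.int8))
        targets = _panel_from(rng.integers(0, 2, size=(4, 30)).astype(np.int8)).subset_sites(
            np.arange(0, 30, 3)
        )
        dos, _ = impute(targets, ref, LSParams())
        assert dos.loo.shape == (4, len(dos.typed_idx))
        assert dos.typed.sum() == len(dos.typed_idx)
        assert (dos.loo >= 0).all() and (dos.loo <= 1).all()


class TestEstimatedR2:
    def test_constant_dosages_zero(self):
        assert estimated_r2(np.full(8, 0.37)) == 0.0

    def test_hard_calls_give_one(self):
        # population-variance of a 0/1 vector equals p(1-p) exactly
        for vec in [[0, 1, 1, 0, 1], [0, 0, 1], [1, 0]]:
            assert estimated_r2(np.array(vec, dtype=float)) == pytest.approx(1.0, abs=1e-12)

    def test_information_scale_endpoints(self):
        assert estimated_r2(np.array([0.5, 0.5, 0.5, 0.5])) == 0.0
        assert estimated_r2(np.array([0.0, 0.0, 1.0, 1.0])) == pytest.approx(1.0)

    def test_degenerate_p_zero_or_one(self):
        assert estimated_r2(np.zeros(6)) == 0.0
        assert estimated_r2(np.ones(6)) == 0.0

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            h = rng.random(rng.integers(2, 30))
            assert 0.0 <= estimated_r2(h) <= 1.0
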