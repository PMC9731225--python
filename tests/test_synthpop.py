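"""Simulator, array design, sample splitting and switch-error injection."""

import numpy as np
import pandas as pd
import pytest

from imputebench import (
    ConfigError,
    PopSpec,
    SimConfig,
    design_array,
    inject_switch_errors,
    simulate_populations,
    split_reference_target,
)

from .conftest import make_panel
from .oracles import hudson_fst


def _config(seed=0, split=100, n_sites=150, ne=150, n=50, pops=("A", "B")):
    return SimConfig(
        n_sites=n_sites,
        seq_length_cM=1.0,
        pops=tuple(PopSpec(p, ne, n) for p in pops),
        split_generations=split,
        seed=seed,
    )


class TestSimulate:
    def test_deterministic_given_seed(self):
        a = simulate_populations(_config(seed=7))
        b = simulate_populations(_config(seed=7))
        for name in a:
            assert np.array_equal(a[name].haplotypes, b[name].haplotypes)
            pd.testing.assert_frame_equal(a[name].sites, b[name].sites)

    def test_different_seeds_differ(self):
        a = simulate_populations(_config(seed=1))["A"]
        b = simulate_populations(_config(seed=2))["A"]
        assert not np.array_equal(a.haplotypes, b.haplotypes)

    def test_af_equals_column_mean(self):
        panels = simulate_populations(_config(seed=3))
        for p in panels.values():
            np.testing.assert_array_equal(p.sites["af"].to_numpy(), p.recompute_af())

    def test_shared_site_set_across_populations(self):
        panels = simulate_populations(_config(seed=4))
        keys = [p.site_keys() for p in panels.values()]
        assert keys[0].equals(keys[1])

    def test_exchangeable_at_split_zero(self):
        """With no post-split drift the two cohorts have matching AF spectra."""
        diffs = []
        for seed in range(8):
            panels = simulate_populations(_config(seed=seed, split=0, n=80))
            diffs.append(
                np.mean(panels["A"].sites["af"].to_numpy() - panels["B"].sites["af"].to_numpy())
            )
        assert abs(np.mean(diffs)) < 0.01

    def test_fst_non_decreasing_in_split_generations(self):
        """Hudson Fst (independent estimator) grows with divergence time."""
        splits = [0, 50, 300]
        n_rep = 20
        means = []
        ses = []
        for split in splits:
            vals = []
            for seed in range(n_rep):
                panels = simulate_populations(_config(seed=seed, split=split, n=60))
                pa, pb = panels["A"], panels["B"]
                maf = np.minimum(pa.sites["af"], 1 - pa.sites["af"])
                common = (maf >= 0.05).to_numpy()
                vals.append(
                    hudson_fst(
                        pa.sites["af"].to_numpy()[common],
                        pb.sites["af"].to_numpy()[common],
                        2 * pa.n_samples,
                        2 * pb.n_samples,
                    )
                )
            means.append(np.mean(vals))
            ses.append(np.std(vals, ddof=1) / np.sqrt(n_rep))
        for lo, hi, se_lo, se_hi in zip(means[:-1], means[1:], ses[:-1], ses[1:]):
            assert hi >= lo - 2 * (se_lo + se_hi)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_sites": 0},
            {"pops": ()},
            {"split": -1},
        ],
    )
    def test_degenerate_config_rejected(self, kwargs):
        split = kwargs.pop("split", 10)
        n_sites = kwargs.pop("n_sites", 50)
        pops = kwargs.pop("pops", (PopSpec("A", 50, 10),))
        with pytest.raises(ConfigError):
            SimConfig(
                n_sites=n_sites,
                seq_length_cM=1.0,
                pops=pops,
                split_generations=split,
            )


class TestDesignArray:
    def test_maf_floor_excludes_monomorphic(self):
        # 12 sites, only 5 polymorphic in the design panel
        h = np.zeros((20, 12), dtype=np.int8)
        h[:10, [1, 3, 5, 7, 9]] = 1  # AF 0.5 at those five
        panel = make_panel(h)
        manifest = design_array(panel, target_density=5, maf_floor=0.05)
        assert set(manifest.sites["pos"]) <= set(panel.sites["pos"].iloc[[1, 3, 5, 7, 9]])
        assert len(manifest) <= 5

    def test_greedy_matches_bruteforce_on_two_ld_blocks(self):
        """Two perfect-LD blocks: any optimal 2-site pick takes one per block."""
        rng = np.random.default_rng(0)
        a = rng.integers(0, 2, 40).astype(np.int8)
        b = rng.integers(0, 2, 40).astype(np.int8)
        h = np.stack([a] * 5 + [b] * 5, axis=1)  # sites 0-4 block A, 5-9 block B
        # ensure both blocks polymorphic and distinct
        assert 0.05 <= a.mean() <= 0.95 and 0.05 <= b.mean() <= 0.95
        panel = make_panel(h)
        manifest = design_array(panel, target_density=2, maf_floor=0.05, ld_r2_tag=0.8)
        picked = panel.site_keys().get_indexer(manifest.site_keys())
        blocks = {0 if j < 5 else 1 for j in picked}
        assert blocks == {0, 1}
        # brute force: best 2-site coverage is all 10 sites
        r2 = np.corrcoef(h, rowvar=False) ** 2
        best = max(
            (r2[[i, j]] >= 0.8).any(axis=0).sum()
            for i in range(10)
            for j in range(i + 1, 10)
        )
        got = (r2[picked] >= 0.8).any(axis=0).sum()
        assert got == best == 10

    def test_matched_design_has_higher_design_pop_maf(self, small_sim_pair):
        pa, pb = small_sim_pair["A"], small_sim_pair["B"]
        arr_a = design_array(pa, 30, design_pop="A")
        arr_b = design_array(pb, 30, design_pop="B")
        maf_a_own = pa.maf()[pa.site_keys().get_indexer(arr_a.site_keys())].mean()
        locs = pa.site_keys().get_indexer(arr_b.site_keys())
        maf_b_in_a = pa.maf()[locs[locs >= 0]].mean()
        assert maf_a_own > maf_b_in_a

    def test_no_site_passes_floor_raises(self):
        panel = make_panel(np.zeros((10, 4), dtype=np.int8))
        with pytest.raises(ValueError, match="MAF floor"):
            design_array(panel, 2)

    def test_manifest_sites_pass_floor_and_are_ordered(self, small_sim_pair):
        panel = small_sim_pair["A"]
        manifest = design_array(panel, 25, maf_floor=0.1)
        locs = panel.site_keys().get_indexer(manifest.site_keys())
        assert (locs >= 0).all()
        assert (panel.maf()[locs] >= 0.1).all()
        assert (np.diff(manifest.sites["pos"]) > 0).all()


class TestSplit:
    def test_partition_arithmetic(self, small_sim_pair):
        panel = small_sim_pair["A"]
        ref, tgt = split_reference_target(panel, 20, seed=5)
        assert ref.n_samples == panel.n_samples - 20
        assert tgt.n_samples == 20
        assert not set(ref.sample_ids) & set(tgt.sample_ids)
        assert set(ref.sample_ids) | set(tgt.sample_ids) == set(panel.sample_ids)

    def test_deterministic(self, small_sim_pair):
        panel = small_sim_pair["A"]
        r1, t1 = split_reference_target(panel, 15, seed=9)
        r2, t2 = split_reference_target(panel, 15, seed=9)
        assert r1.sample_ids == r2.sample_ids
        assert np.array_equal(t1.haplotypes, t2.haplotypes)

    def test_n_target_too_large_raises(self, small_sim_pair):
        panel = small_sim_pair["A"]
        with pytest.raises(ValueError):
            split_reference_target(panel, panel.n_samples, seed=0)


class TestSwitchErrors:
    def test_rate_zero_is_identity(self, small_sim_pair):
        panel = small_sim_pair["A"]
        out = inject_switch_errors(panel, 0.0, seed=1)
        assert np.array_equal(out.haplotypes, panel.haplotypes)

    def test_genotypes_preserved_at_any_rate(self, small_sim_pair):
        panel = small_sim_pair["A"]
        for rate in [0.05, 0.5, 1.0]:
            out = inject_switch_errors(panel, rate, seed=2)
            assert np.array_equal(out.diploid_dosages(), panel.diploid_dosages())

    def test_rate_one_alternates_assignment(self):
        # one sample, two het sites: hand-traced toggling.  The orientation
        # flips at the first het site (swap) and flips back at the second.
        h = np.array([[1, 0], [0, 1]], dtype=np.int8)
        panel = make_panel(h)
        out = inject_switch_errors(panel, 1.0, seed=0)
        assert out.haplotypes.tolist() == [[0, 0], [1, 1]]
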