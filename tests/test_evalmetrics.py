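"""Aggregated R^2, % well-imputed and report comparison."""

import numpy as np
import pandas as pd
import pytest

from imputebench import (
    AFBinSpec,
    aggregated_r2,
    compare_reports,
    evaluate,
    pct_well_imputed,
)
from imputebench.lsimpute import DosageSet

from .conftest import make_panel


def make_dosage_set(hds, sites=None, typed_idx=(), est_r2=None, panel_id="P", af=None):
    hds = np.asarray(hds, dtype=np.float64)
    n_haps, n_sites = hds.shape
    if sites is None:
        sites = pd.DataFrame(
            {
                "contig": "1",
                "pos": np.arange(n_sites) * 1000 + 100,  # matches make_panel
                "ref": "A",
                "alt": "G",
            }
        )
    typed_idx = np.asarray(typed_idx, dtype=np.int64)
    sites = sites.copy()
    sites["typed"] = False
    sites.loc[typed_idx, "typed"] = True
    sites["af"] = hds.mean(axis=0) if af is None else np.asarray(af)
    if est_r2 is None:
        est_r2 = np.ones(n_sites)
    return DosageSet(
        sites=sites,
        hds=hds,
        loo=hds[:, typed_idx],
        typed_idx=typed_idx,
        est_r2=np.asarray(est_r2, dtype=np.float64),
        sample_ids=[f"S{i}" for i in range(n_haps // 2)],
        panel_id=panel_id,
    )


def truth_from_ds(ds):
    """Phased truth panel whose diploid dosages equal ``ds`` exactly."""
    ds = np.asarray(ds)
    n, s = ds.shape
    haps = np.zeros((2 * n, s), dtype=np.int8)
    haps[0::2] = (ds >= 1).astype(np.int8)
    haps[1::2] = (ds == 2).astype(np.int8)
    return make_panel(haps)


class TestAggregatedR2:
    def test_perfect_dosages_score_one(self):
        rng = np.random.default_rng(0)
        truth_ds = rng.integers(0, 3, size=(20, 12))
        truth = truth_from_ds(truth_ds)
        hds = np.zeros((40, 12))
        hds[0::2] = (truth_ds >= 1).astype(float)
        hds[1::2] = (truth_ds == 2).astype(float)
        dos = make_dosage_set(hds)
        rep = aggregated_r2(dos, truth, AFBinSpec())
        t = rep.table[rep.table["defined"]]
        assert len(t) >= 1
        assert np.allclose(t["mean_r2"], 1.0, atol=1e-9)
        assert rep.overall_mean_r2 == pytest.approx(1.0, abs=1e-9)

    def test_single_site_matches_hand_calculation(self):
        # ds = (0.1, 0.9, 1.8, 0.2) vs truth (0, 1, 2, 0):
        # Pearson r computed by hand: r^2 = 0.99320388349514561...
        ds = np.array([[0.1], [0.9], [1.8], [0.2]])
        truth = truth_from_ds(np.array([[0], [1], [2], [0]]))
        hds = np.zeros((8, 1))
        hds[0::2, 0] = ds[:, 0] / 2
        hds[1::2, 0] = ds[:, 0] / 2
        dos = make_dosage_set(hds)
        rep = aggregated_r2(dos, truth, AFBinSpec())
        got = rep.table.loc[rep.table["defined"], "mean_r2"].iloc[0]
        x = ds[:, 0]
        y = np.array([0.0, 1.0, 2.0, 0.0])
        num = ((x - x.mean()) * (y - y.mean())).sum()
        den = np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert got == pytest.approx((num / den) ** 2, abs=1e-12)

    def test_constant_dosage_excluded_with_count(self):
        truth = truth_from_ds(np.array([[0, 0], [1, 1], [2, 2], [0, 0]]))
        hds = np.zeros((8, 2))
        hds[:, 0] = 0.4  # constant at a polymorphic truth site
        hds[0::2, 1] = [0, 0.5, 1, 0]
        hds[1::2, 1] = [0, 0.5, 1, 0]
        dos = make_dosage_set(hds)
        rep = aggregated_r2(dos, truth, AFBinSpec())
        assert rep.n_zero_variance_excluded == 1
        assert rep.table["n_sites"].sum() == 1

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(1)
        truth_ds = rng.integers(0, 3, size=(30, 6))
        truth = truth_from_ds(truth_ds)
        hds = rng.random((60, 6))
        dos1 = make_dosage_set(hds)
        dos2 = make_dosage_set(0.3 * hds + 0.2)
        r1 = aggregated_r2(dos1, truth, AFBinSpec())
        r2 = aggregated_r2(dos2, truth, AFBinSpec())
        pd.testing.assert_series_equal(r1.table["mean_r2"], r2.table["mean_r2"])

    def test_sample_mismatch_raises(self):
        truth = truth_from_ds(np.zeros((3, 2), dtype=int))
        dos = make_dosage_set(np.random.default_rng(2).random((8, 2)))
        with pytest.raises(ValueError):
            aggregated_r2(dos, truth, AFBinSpec())


class TestPctWellImputed:
    def test_counting_arithmetic(self):
        hds = np.tile([[0.0], [1.0]], (2, 4)).reshape(4, 4)
        dos = make_dosage_set(
            np.random.default_rng(3).random((6, 4)),
            est_r2=[0.9, 0.85, 0.7, 0.95],
            af=[0.3, 0.3, 0.3, 0.3],
        )
        rep = pct_well_imputed(dos, AFBinSpec(), threshold=0.8)
        common = rep.table.iloc[-1]
        assert common["pct_well_imputed"] == 75.0
        assert common["n_well_imputed"] == 3

    def test_all_typed_is_undefined(self):
        dos = make_dosage_set(
            np.random.default_rng(4).random((6, 3)),
            typed_idx=[0, 1, 2],
            af=[0.2, 0.3, 0.4],
        )
        rep = pct_well_imputed(dos, AFBinSpec())
        assert not rep.table["defined"].any()
        assert rep.table["pct_well_imputed"].isna().all()

    def test_zero_threshold_gives_hundred_percent(self):
        dos = make_dosage_set(
            np.random.default_rng(5).random((6, 5)),
            est_r2=[0.0, 0.1, 0.5, 0.9, 0.2],
            af=[0.1, 0.2, 0.3, 0.4, 0.5],
        )
        rep = pct_well_imputed(dos, AFBinSpec(), threshold=0.0)
        t = rep.table[rep.table["defined"]]
        assert (t["pct_well_imputed"] == 100.0).all()

    def test_typed_sites_excluded_from_both_sides(self):
        dos = make_dosage_set(
            np.random.default_rng(6).random((6, 4)),
            typed_idx=[0],
            est_r2=[1.0, 0.9, 0.1, 0.9],
            af=[0.3, 0.3, 0.3, 0.3],
        )
        rep = pct_well_imputed(dos, AFBinSpec())
        common = rep.table.iloc[-1]
        assert common["n_imputed"] == 3
        assert common["n_well_imputed"] == 2


class TestBins:
    def test_default_bins_partition(self):
        bins = AFBinSpec()
        rng = np.random.default_rng(7)
        af = rng.uniform(1e-6, 1.0, 500)
        idx = bins.assign(af)
        assert ((idx >= 0) & (idx < bins.n_bins)).all()
        # each AF falls in exactly one bin; counts sum to total
        counts = np.bincount(idx, minlength=bins.n_bins)
        assert counts.sum() == af.size

    def test_bin_edges_and_labels(self):
        bins = AFBinSpec()
        assert bins.labels == ["<0.2%", "0.2%-0.5%", "0.5%-5%", ">=5%"]
        assert list(bins.assign(np.array([0.001, 0.002, 0.004, 0.005, 0.04, 0.05, 0.9]))) == [
            0, 1, 1, 2, 2, 3, 3,
        ]
        assert bins.assign(np.array([0.0, -1.0, 1.5])).tolist() == [-1, -1, -1]

    def test_invalid_edges_rejected(self):
        with pytest.raises(ValueError):
            AFBinSpec(edges=(0.5, 0.1))


class TestCompareReports:
    def _reports(self, n=2):
        rng = np.random.default_rng(8)
        truth_ds = rng.integers(0, 3, size=(20, 10))
        truth = truth_from_ds(truth_ds)
        reports = []
        for i in range(n):
            hds = rng.random((40, 10))
            reports.append(evaluate(make_dosage_set(hds, panel_id=f"P{i}"), truth))
        return reports

    def test_identical_reports_tie(self):
        from imputebench import EvalReport

        rep = self._reports(1)[0]
        rep2 = EvalReport(
            panel_id="Q",
            bins=rep.bins,
            table=rep.table.copy(),
            overall_mean_r2=rep.overall_mean_r2,
            n_zero_variance_excluded=rep.n_zero_variance_excluded,
        )
        long = compare_reports([rep, rep2])
        piv = long.pivot_table(index=["bin", "metric"], columns="panel", values="value")
        assert np.allclose(piv.iloc[:, 0], piv.iloc[:, 1], equal_nan=True)

    def test_table_shape(self):
        reps = self._reports(3)
        long = compare_reports(reps)
        n_metrics = long["metric"].nunique()
        assert len(long) == 3 * 4 * n_metrics

    def test_bin_mismatch_raises(self):
        reps = self._reports(2)
        other = evaluate(
            make_dosage_set(np.random.default_rng(9).random((40, 10))),
            truth_from_ds(np.random.default_rng(8).integers(0, 3, size=(20, 10))),
            AFBinSpec(edges=(0.01, 0.1)),
        )
        with pytest.raises(ValueError, match="bins"):
            compare_reports([reps[0], other])

    def test_fewer_than_two_raises(self):
        with pytest.raises(ValueError):
            compare_reports(self._reports(1))
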