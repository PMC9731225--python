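"""Imputation accuracy metrics binned by non-reference allele frequency.

Two complementary statistics are computed per allele-frequency bin:

* aggregated R^2 — the squared Pearson correlation between imputed diploid
  dosages and true genotype dosages, computed per site across samples and
  summarized per bin (mean and SD over sites, plus a pooled variant that
  correlates all (site, sample) pairs in the bin at once);
* % well-imputed — the share of imputed sites whose model-internal
  estimated r^2 reaches a threshold (0.8 by default, with a relaxed 0.4
  companion).

Bins follow the conventional rare-to-common split on non-reference allele
frequency: >= 5 %, 0.5-5 %, 0.2-0.5 % and < 0.2 %.  The binning frequency
is the truth panel's AF over the evaluation samples by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lsimpute import DosageSet
from .synthpop import MISSING, HaplotypePanel

__all__ = [
    "AFBinSpec",
    "EvalReport",
    "aggregated_r2",
    "pct_well_imputed",
    "evaluate",
    "compare_reports",
]

DEFAULT_BIN_EDGES = (0.002, 0.005, 0.05)


@dataclass(frozen=True)
class AFBinSpec:
    """Ordered allele-frequency bins partitioning (0, 1].

    ``edges`` are the interior cut points; bin *i* spans
    ``[edges[i-1], edges[i])`` with the first bin open at 0 and the last
    closed at 1.  ``af_source`` records which AF defines the bin ("truth"
    or "panel").
    """

    edges: tuple[float, ...] = DEFAULT_BIN_EDGES
    af_source: str = "truth"

    def __post_init__(self) -> None:
        e = self.edges
        if not all(0.0 < a < 1.0 for a in e) or list(e) != sorted(set(e)):
            raise ValueError("edges must be strictly increasing within (0, 1)")

    @property
    def labels(self) -> list[str]:
        def fmt(x: float) -> str:
            pct = x * 100
            return f"{pct:g}%"

        e = self.edges
        labels = [f"<{fmt(e[0])}"]
        labels += [f"{fmt(a)}-{fmt(b)}" for a, b in zip(e[:-1], e[1:])]
        labels.append(f">={fmt(e[-1])}")
        return labels

    @property
    def n_bins(self) -> int:
        return len(self.edges) + 1

    def assign(self, af: np.ndarray) -> np.ndarray:
        """Bin index per site; -1 for AF outside (0, 1]."""
        af = np.asarray(af, dtype=np.float64)
        idx = np.searchsorted(np.asarray(self.edges), af, side="right")
        idx[(af <= 0.0) | (af > 1.0)] = -1
        return idx


@dataclass
class EvalReport:
    """Per-bin accuracy summary for one panel's imputation of one cohort.

    ``table`` has one row per AF bin with columns ``bin``, ``n_sites``,
    ``mean_r2``, ``sd_r2``, ``pooled_r2``, ``n_imputed``,
    ``n_well_imputed``, ``pct_well_imputed``, ``pct_well_imputed_relaxed``
    and ``defined`` (False where a bin has no imputed sites, in which case
    percentages are NaN, not 0).
    """

    panel_id: str
    bins: AFBinSpec
    table: pd.DataFrame
    overall_mean_r2: float
    n_zero_variance_excluded: int = 0

    def to_dict(self) -> dict:
        return {
            "panel_id": self.panel_id,
            "bin_edges": list(self.bins.edges),
            "af_source": self.bins.af_source,
            "overall_mean_r2": self.overall_mean_r2,
            "n_zero_variance_excluded": self.n_zero_variance_excluded,
            "table": self.table.replace({np.nan: None}).to_dict(orient="records"),
        }


def _truth_af(truth: HaplotypePanel, cols: np.ndarray) -> np.ndarray:
    return truth.recompute_af()[cols]


def _per_site_r2(ds: np.ndarray, truth_ds: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Squared Pearson correlation per column; second array flags validity."""
    x = ds - ds.mean(axis=0)
    y = truth_ds - truth_ds.mean(axis=0)
    sx = (x * x).sum(axis=0)
    sy = (y * y).sum(axis=0)
    valid = (sx > 0) & (sy > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (x * y).sum(axis=0) / np.sqrt(np.where(valid, sx * sy, 1.0))
    r2 = np.where(valid, r * r, np.nan)
    return r2, valid


def aggregated_r2(
    dosages: DosageSet,
    truth: HaplotypePanel,
    bins: AFBinSpec = AFBinSpec(),
    include_typed: bool = False,
) -> EvalReport:
    """Aggregated R^2 of imputed dosages against truth, per AF bin.

    Per-site R^2 is the squared Pearson correlation between the diploid
    imputed dosage and the true genotype dosage across the (identical)
    samples; sites monomorphic in truth or with constant dosage are
    excluded and counted.  Typed sites are excluded unless
    ``include_typed``.  The binning AF is the truth AF of the evaluation
    samples.
    """
    if dosages.sample_ids != truth.sample_ids:
        raise ValueError("dosage and truth sample sets differ")

    truth_keys = truth.site_keys()
    locs = truth_keys.get_indexer(dosages.site_keys())
    eval_mask = locs >= 0
    if not include_typed:
        eval_mask &= ~dosages.typed
    d_cols = np.flatnonzero(eval_mask)
    t_cols = locs[d_cols]

    ds = dosages.ds[:, d_cols]
    truth_ds = truth.diploid_dosages()[:, t_cols].astype(np.float64)
    r2, valid = _per_site_r2(ds, truth_ds)
    af = _truth_af(truth, t_cols)
    bin_idx = bins.assign(af)

    rows = []
    included = valid & (bin_idx >= 0)
    for b, label in enumerate(bins.labels):
        sel = included & (bin_idx == b)
        vals = r2[sel]
        rows.append(
            {
                "bin": label,
                "n_sites": int(sel.sum()),
                "mean_r2": float(np.mean(vals)) if vals.size else np.nan,
                "sd_r2": float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan,
                "pooled_r2": _pooled_r2(ds[:, sel], truth_ds[:, sel]),
                "n_imputed": 0,
                "n_well_imputed": 0,
                "pct_well_imputed": np.nan,
                "pct_well_imputed_relaxed": np.nan,
                "defined": bool(vals.size),
            }
        )
    table = pd.DataFrame(rows)
    all_vals = r2[included]
    return EvalReport(
        panel_id=dosages.panel_id,
        bins=bins,
        table=table,
        overall_mean_r2=float(np.mean(all_vals)) if all_vals.size else np.nan,
        n_zero_variance_excluded=int((~valid).sum()),
    )


def _pooled_r2(ds: np.ndarray, truth_ds: np.ndarray) -> float:
    """Squared correlation over all (site, sample) pairs at once."""
    if ds.size == 0:
        return np.nan
    x = ds.ravel()
    y = truth_ds.ravel()
    if x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def pct_well_imputed(
    dosages: DosageSet,
    bins: AFBinSpec = AFBinSpec(),
    threshold: float = 0.8,
    relaxed_threshold: float = 0.4,
    af: np.ndarray | None = None,
) -> EvalReport:
    """Share of imputed sites whose estimated r^2 reaches the threshold.

    Typed sites are excluded from numerator and denominator.  Bins with no
    imputed sites report NaN (undefined), flagged via ``defined``.  ``af``
    overrides the binning AF (defaults to the dosage set's stored panel AF).
    """
    imputed = ~dosages.typed
    af = dosages.sites["af"].to_numpy() if af is None else np.asarray(af)
    bin_idx = bins.assign(af)
    est = dosages.est_r2

    rows = []
    for b, label in enumerate(bins.labels):
        sel = imputed & (bin_idx == b)
        n = int(sel.sum())
        n_well = int((est[sel] >= threshold).sum())
        n_rel = int((est[sel] >= relaxed_threshold).sum())
        rows.append(
            {
                "bin": label,
                "n_sites": n,
                "mean_r2": np.nan,
                "sd_r2": np.nan,
                "pooled_r2": np.nan,
                "n_imputed": n,
                "n_well_imputed": n_well,
                "pct_well_imputed": 100.0 * n_well / n if n else np.nan,
                "pct_well_imputed_relaxed": 100.0 * n_rel / n if n else np.nan,
                "defined": bool(n),
            }
        )
    table = pd.DataFrame(rows)
    return EvalReport(
        panel_id=dosages.panel_id,
        bins=bins,
        table=table,
        overall_mean_r2=np.nan,
    )


def evaluate(
    dosages: DosageSet,
    truth: HaplotypePanel,
    bins: AFBinSpec = AFBinSpec(),
    threshold: float = 0.8,
    relaxed_threshold: float = 0.4,
) -> EvalReport:
    """Full per-bin report: aggregated R^2 plus % well-imputed.

    With ``bins.af_source == "truth"`` (default) both metrics are binned on
    the truth AF of the evaluation samples, so a site falls in the same bin
    for either statistic; with ``"panel"`` the % well-imputed is binned on
    the reference-panel AF stored in the dosage set, which resolves rarer
    bins than a small truth cohort can.
    """
    r2_rep = aggregated_r2(dosages, truth, bins)

    if bins.af_source == "panel":
        af = dosages.sites["af"].to_numpy()
    else:
        locs = truth.site_keys().get_indexer(dosages.site_keys())
        af = np.full(len(dosages.sites), -1.0)
        present = locs >= 0
        af[present] = truth.recompute_af()[locs[present]]
    pct_rep = pct_well_imputed(
        dosages, bins, threshold=threshold, relaxed_threshold=relaxed_threshold, af=af
    )

    table = r2_rep.table.copy()
    for col in ["n_imputed", "n_well_imputed", "pct_well_imputed", "pct_well_imputed_relaxed"]:
        table[col] = pct_rep.table[col]
    table["defined"] = r2_rep.table["defined"] | pct_rep.table["defined"]
    return EvalReport(
        panel_id=dosages.panel_id,
        bins=bins,
        table=table,
        overall_mean_r2=r2_rep.overall_mean_r2,
        n_zero_variance_excluded=r2_rep.n_zero_variance_excluded,
    )


def compare_reports(reports: list[EvalReport]) -> pd.DataFrame:
    """Long-format comparison of >= 2 reports sharing the same bins.

    Returns rows (panel, bin, metric, value, rank) with rank 1 given to the
    best panel per (bin, metric); deterministic ordering by panel then bin.
    """
    if len(reports) < 2:
        raise ValueError("at least two reports are required")
    edges = reports[0].bins.edges
    for r in reports[1:]:
        if r.bins.edges != edges:
            raise ValueError("reports use different AF bins")

    metrics = ["mean_r2", "sd_r2", "pooled_r2", "pct_well_imputed", "pct_well_imputed_relaxed"]
    rows = []
    for rep in reports:
        for _, row in rep.table.iterrows():
            for m in metrics:
                rows.append(
                    {"panel": rep.panel_id, "bin": row["bin"], "metric": m, "value": row[m]}
                )
    long = pd.DataFrame(rows)
    # rank 1 = best; SD ranks ascending (smaller spread is better)
    # (plotting of the comparison lives in plot_bin_metric)
    ranks = np.full(len(long), np.nan)
    for (_, metric), grp in long.groupby(["bin", "metric"], sort=False):
        asc = metric == "sd_r2"
        ranks[grp.index] = grp["value"].rank(ascending=asc, method="min")
    long["rank"] = ranks
    return long.reset_index(drop=True)


def plot_bin_metric(
    reports: list[EvalReport],
    metric: str = "mean_r2",
    path: str | None = None,
):
    """Basic bin-vs-metric comparison figure (one line per panel).

    Requires matplotlib (optional dependency); returns the figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for rep in reports:
        ax.plot(rep.table["bin"], rep.table[metric], marker="o", label=rep.panel_id)
    ax.set_xlabel("non-reference allele frequency bin")
    ax.set_ylabel(metric)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
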