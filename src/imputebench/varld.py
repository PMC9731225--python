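"""Windowed comparison of LD structure between two populations (varLD).

For each sliding window of consecutive common sites, the signed pairwise
correlation matrix of genotype dosages is computed in each population and
eigendecomposed; the raw score is the L1 distance between the two
descending-sorted eigenvalue spectra.  Raw scores are standardized to
zero mean and unit SD across windows, and maximal runs of windows above
the top-percentile cutoff (nearest-rank) are merged into candidate regions
of population-specific LD architecture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthpop import MISSING, HaplotypePanel

__all__ = [
    "VarLDConfig",
    "WindowScore",
    "varld_raw_score",
    "window_scores",
    "standardize_and_call",
    "varld_scan",
]


@dataclass(frozen=True)
class VarLDConfig:
    """Scan parameters: sites per window, slide step, MAF floor for site
    inclusion and the percentile used for region calls."""

    window_size: int = 50
    step: int | None = None  # default window_size // 2
    top_pct: float = 1.0
    min_maf: float = 0.05

    def __post_init__(self) -> None:
        if self.window_size < 2:
            raise ValueError("window_size must be >= 2")
        if not (0.0 < self.top_pct < 100.0):
            raise ValueError("top_pct must lie in (0, 100)")
        if self.step is not None and self.step < 1:
            raise ValueError("step must be >= 1")

    @property
    def effective_step(self) -> int:
        return self.step if self.step is not None else max(1, self.window_size // 2)


@dataclass
class WindowScore:
    """One window: physical span, raw score, standardized score."""

    contig: str
    start: int
    end: int  # half-open bp span
    raw: float
    standardized: float = math.nan


def varld_raw_score(
    geno_A: np.ndarray, geno_B: np.ndarray
) -> tuple[float, int]:
    """Raw LD-divergence score for one window of genotype dosages.

    ``geno_A``/``geno_B`` are (n_samples, n_sites) dosage matrices over the
    same ordered sites.  Sites with zero variance in either population are
    dropped pairwise (count returned); with < 2 variable sites the score is
    undefined and NaN is returned.  The score is
    ``sum_i |lambda_i^A - lambda_i^B|`` over descending-sorted eigenvalues
    of the two signed correlation matrices.
    """
    a = np.asarray(geno_A, dtype=np.float64)
    b = np.asarray(geno_B, dtype=np.float64)
    if a.shape[1] != b.shape[1]:
        raise ValueError("windows must cover the same ordered site set")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("at least two samples per population are required")
    keep = (a.std(axis=0) > 0) & (b.std(axis=0) > 0)
    dropped = int((~keep).sum())
    if keep.sum() < 2:
        return math.nan, dropped
    ra = np.corrcoef(a[:, keep], rowvar=False)
    rb = np.corrcoef(b[:, keep], rowvar=False)
    ev_a = np.sort(np.linalg.eigvalsh(ra))[::-1]
    ev_b = np.sort(np.linalg.eigvalsh(rb))[::-1]
    return float(np.abs(ev_a - ev_b).sum()), dropped


def window_scores(
    pop_a: HaplotypePanel,
    pop_b: HaplotypePanel,
    config: VarLDConfig = VarLDConfig(),
) -> list[WindowScore]:
    """Raw scores over sliding windows of shared common sites.

    Sites are restricted to those shared by both panels with MAF >=
    ``min_maf`` in both populations; windows of ``window_size`` such sites
    slide by ``step`` sites.  Windows whose score is undefined (< 2 variable
    sites after pairwise drops) are skipped.
    """
    keys_a = pop_a.site_keys()
    shared = keys_a.get_indexer(pop_b.site_keys())
    cols_b = np.flatnonzero(shared >= 0)
    cols_a = shared[cols_b]

    ga = pop_a.diploid_dosages()[:, cols_a]
    gb = pop_b.diploid_dosages()[:, cols_b]
    maf_a = pop_a.maf()[cols_a]
    maf_b = pop_b.maf()[cols_b]
    common = (maf_a >= config.min_maf) & (maf_b >= config.min_maf)
    ga, gb = ga[:, common], gb[:, common]
    pos = pop_a.sites["pos"].to_numpy()[cols_a][common]
    contig = pop_a.sites["contig"].to_numpy()[cols_a][common]

    n = ga.shape[1]
    out: list[WindowScore] = []
    step = config.effective_step
    for start in range(0, max(n - config.window_size + 1, 0), step):
        sl = slice(start, start + config.window_size)
        if len(set(contig[sl])) != 1:
            continue
        raw, _ = varld_raw_score(ga[:, sl], gb[:, sl])
        if math.isnan(raw):
            continue
        out.append(
            WindowScore(
                contig=str(contig[start]),
                start=int(pos[sl][0]),
                end=int(pos[sl][-1]) + 1,
                raw=raw,
            )
        )
    return out


def standardize_and_call(
    raw_scores: list[WindowScore],
    config: VarLDConfig = VarLDConfig(),
) -> tuple[list[WindowScore], pd.DataFrame]:
    """Standardize window scores and call top-percentile regions.

    Standardization subtracts the mean and divides by the SD of the raw
    scores over all windows; the call threshold is the nearest-rank
    ``100 - top_pct`` percentile of the standardized scores, and adjacent
    or overlapping windows above it merge into half-open bp regions.
    """
    if len(raw_scores) < 10:
        raise ValueError("at least 10 windows are required")
    raw = np.array([w.raw for w in raw_scores])
    sd = raw.std()
    if sd == 0:
        raise ValueError("zero variance across windows: degenerate input")
    z = (raw - raw.mean()) / sd
    scored = [
        WindowScore(w.contig, w.start, w.end, w.raw, float(s))
        for w, s in zip(raw_scores, z)
    ]

    # nearest-rank percentile: smallest value with rank >= ceil(q/100 * n)
    n = len(z)
    rank = max(1, math.ceil((100.0 - config.top_pct) / 100.0 * n))
    cutoff = np.sort(z)[rank - 1]
    hits = [w for w in scored if w.standardized > cutoff]

    regions: list[dict] = []
    for w in sorted(hits, key=lambda w: (w.contig, w.start)):
        if regions and regions[-1]["contig"] == w.contig and w.start <= regions[-1]["end"]:
            regions[-1]["end"] = max(regions[-1]["end"], w.end)
            regions[-1]["max_standardized"] = max(
                regions[-1]["max_standardized"], w.standardized
            )
        else:
            regions.append(
                {
                    "contig": w.contig,
                    "start": w.start,
                    "end": w.end,
                    "max_standardized": w.standardized,
                }
            )
    return scored, pd.DataFrame(regions, columns=["contig", "start", "end", "max_standardized"])


def varld_scan(
    pop_a: HaplotypePanel,
    pop_b: HaplotypePanel,
    config: VarLDConfig = VarLDConfig(),
) -> tuple[list[WindowScore], pd.DataFrame]:
    """Convenience wrapper: window scores, standardization and region calls."""
    return standardize_and_call(window_scores(pop_a, pop_b, config), config)
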