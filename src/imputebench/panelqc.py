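"""Reference-panel quality control.

Variant-level filter cascade used when building a haplotype reference panel
from population sequencing data: per-site missingness, an exact
Hardy-Weinberg equilibrium test, low-complexity region masking, removal of
indels, multi-allelic sites, singletons and monomorphic sites, and a
cross-dataset presence filter that keeps only sites seen in enough
external sequencing datasets.
Every removal is attributed to the first filter that triggers, so the audit
counts plus the survivors always add back up to the input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthpop import MISSING, HaplotypePanel

__all__ = [
    "QCThresholds",
    "QCReport",
    "hwe_exact_test",
    "apply_qc_cascade",
    "FILTER_ORDER",
]

FILTER_ORDER = (
    "missingness",
    "hwe",
    "region_mask",
    "indel",
    "multiallelic",
    "singleton",
    "monomorphic",
    "external_presence",
)


@dataclass(frozen=True)
class QCThresholds:
    """Thresholds of the reference-panel filter cascade.

    Defaults: exclude sites with exact HWE p < 1e-6, per-site genotype
    missing rate > 5 %, indels, sites with more than 10 alternative
    alleles, singletons (non-reference allele count = 1), monomorphic
    sites (no segregating variant), and sites present in fewer than
    ``min_external_datasets`` of the supplied external site lists.
    """

    hwe_p_max_exclusive: float = 1e-6
    missing_rate_max: float = 0.05
    max_alt_alleles: int = 10
    drop_indels: bool = True
    drop_singletons: bool = True
    drop_monomorphic: bool = True
    min_external_datasets: int = 2

    def __post_init__(self) -> None:
        if not (0.0 <= self.hwe_p_max_exclusive <= 1.0):
            raise ValueError("hwe_p_max_exclusive must lie in [0, 1]")
        if not (0.0 <= self.missing_rate_max <= 1.0):
            raise ValueError("missing_rate_max must lie in [0, 1]")
        if self.max_alt_alleles < 1:
            raise ValueError("max_alt_alleles must be >= 1")
        if self.min_external_datasets < 0:
            raise ValueError("min_external_datasets must be >= 0")


@dataclass
class QCReport:
    """Audit trail of one cascade run: per-filter removals in order."""

    n_input_sites: int
    removals: dict[str, int]
    n_surviving_sites: int
    n_samples: int

    def __post_init__(self) -> None:
        if self.n_input_sites - sum(self.removals.values()) != self.n_surviving_sites:
            raise ValueError("removal counts do not account for survivors")

    def to_dict(self) -> dict:
        return {
            "n_input_sites": self.n_input_sites,
            "removals": dict(self.removals),
            "n_surviving_sites": self.n_surviving_sites,
            "n_samples": self.n_samples,
        }


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value from genotype counts.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote configurations no more likely than the observed one
    (the standard exact formulation for biallelic genotype data).  Symmetric
    in swapping the two homozygote counts.  Returns a value in (0, 1].
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotype is required")

    n_rare = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)  # rarer allele count
    if n_rare == 0:
        return 1.0

    # Unnormalized probabilities over all het counts with the parity of n_rare,
    # built by the standard two-sided recurrence from the mode outward.
    mid = int(round(n_rare * (2 * n - n_rare) / (2.0 * n)))
    if (mid % 2) != (n_rare % 2):
        mid += 1
    het_max = n_rare
    mid = min(mid, het_max)
    probs = np.zeros(het_max + 1)
    probs[mid] = 1.0
    # downward: P(het-2) = P(het) * het*(het-1) / ((n_rare-het+2)*(n_common-het+2))
    het = mid
    while het >= 2:
        hom_r = (n_rare - het) // 2
        hom_c = n - het - hom_r
        probs[het - 2] = probs[het] * het * (het - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        het -= 2
    het = mid
    while het <= het_max - 2:
        hom_r = (n_rare - het) // 2
        hom_c = n - het - hom_r
        probs[het + 2] = probs[het] * 4.0 * hom_r * hom_c / ((het + 1) * (het + 2))
        het += 2
    probs /= probs.sum()
    obs = probs[n_Aa]
    return float(min(1.0, probs[probs <= obs * (1.0 + 1e-12)].sum()))


def _genotype_counts(panel: HaplotypePanel) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (n_hom_ref, n_het, n_hom_alt, missing_rate) from diploids."""
    ds = panel.diploid_dosages()
    miss = ds == MISSING
    n_rr = ((ds == 0)).sum(axis=0)
    n_ra = ((ds == 1)).sum(axis=0)
    n_aa = ((ds == 2)).sum(axis=0)
    miss_rate = miss.mean(axis=0)
    return n_rr, n_ra, n_aa, miss_rate


def _in_mask(sites: pd.DataFrame, intervals: pd.DataFrame) -> np.ndarray:
    """True where a site lies within any half-open [start, end) interval."""
    hit = np.zeros(len(sites), dtype=bool)
    if intervals is None or len(intervals) == 0:
        return hit
    for contig, grp in intervals.groupby("contig", sort=False):
        on = sites["contig"].to_numpy() == contig
        if not on.any():
            continue
        pos = sites["pos"].to_numpy()[on]
        sub = np.zeros(pos.size, dtype=bool)
        for start, end in zip(grp["start"], grp["end"]):
            sub |= (pos >= start) & (pos < end)
        hit[np.flatnonzero(on)] |= sub
    return hit


def apply_qc_cascade(
    panel: HaplotypePanel,
    region_mask: pd.DataFrame | None = None,
    external_site_lists: list[set] | None = None,
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[HaplotypePanel, QCReport]:
    """Apply the reference-panel filter cascade and return survivors + audit.

    Filters run in the fixed order missingness -> HWE -> region mask ->
    indel -> multi-allelic -> singleton -> monomorphic -> external
    presence; each removed
    site is counted at the first filter that triggers.  ``region_mask`` is a
    DataFrame with columns ``contig``, ``start``, ``end`` (0-based
    half-open); ``external_site_lists`` holds sets of
    ``(contig, pos, ref, alt)`` keys.  The output panel contains sorted
    biallelic SNVs only.
    """
    external_site_lists = external_site_lists or []
    sites = panel.sites
    n_in = len(sites)
    n_rr, n_ra, n_aa, miss_rate = _genotype_counts(panel)
    ac = panel.allele_counts()

    fail = {}
    fail["missingness"] = miss_rate > thresholds.missing_rate_max

    hwe_p = np.ones(n_in)
    for j in range(n_in):
        tot = n_rr[j] + n_ra[j] + n_aa[j]
        if tot > 0:
            hwe_p[j] = hwe_exact_test(int(n_rr[j]), int(n_ra[j]), int(n_aa[j]))
    fail["hwe"] = hwe_p < thresholds.hwe_p_max_exclusive

    fail["region_mask"] = _in_mask(sites, region_mask)

    ref = sites["ref"].astype(str)
    alt = sites["alt"].astype(str)
    alt_alleles = alt.str.split(",")
    is_indel = (ref.str.len() > 1) | alt_alleles.apply(
        lambda xs: any(len(a) > 1 for a in xs)
    )
    fail["indel"] = is_indel.to_numpy() if thresholds.drop_indels else np.zeros(n_in, bool)

    n_alt = alt_alleles.apply(len).to_numpy()
    fail["multiallelic"] = n_alt > thresholds.max_alt_alleles
    # multi-allelic records (any site with >1 ALT) cannot survive as biallelic SNVs
    fail["multiallelic"] |= n_alt > 1

    fail["singleton"] = (
        (ac == 1) if thresholds.drop_singletons else np.zeros(n_in, bool)
    )

    # a reference panel carries segregating variants only: sites with no
    # observed alternative allele, or fixed for it, are not variants
    n_obs_alleles = 2 * (n_rr + n_ra + n_aa)
    fail["monomorphic"] = (
        ((ac == 0) | (ac == n_obs_alleles))
        if thresholds.drop_monomorphic
        else np.zeros(n_in, bool)
    )

    if thresholds.min_external_datasets > 0:
        keys = list(zip(sites["contig"], sites["pos"], sites["ref"], sites["alt"]))
        presence = np.zeros(n_in, dtype=np.int64)
        for ext in external_site_lists:
            presence += np.fromiter((k in ext for k in keys), dtype=np.int64, count=n_in)
        fail["external_presence"] = presence < thresholds.min_external_datasets
    else:
        fail["external_presence"] = np.zeros(n_in, dtype=bool)

    removals: dict[str, int] = {}
    removed = np.zeros(n_in, dtype=bool)
    for name in FILTER_ORDER:
        newly = fail[name] & ~removed
        removals[name] = int(newly.sum())
        removed |= newly

    keep = np.flatnonzero(~removed)
    out = panel.subset_sites(keep)
    report = QCReport(
        n_input_sites=n_in,
        removals=removals,
        n_surviving_sites=len(keep),
        n_samples=panel.n_samples,
    )
    return out, report
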