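"""Array-mimicking genotype panels.

A genotyping array observes only its manifest sites, and imputation
pipelines drop typed sites that are rare in the target cohort before
pre-phasing.  ``mask_to_array`` reproduces both steps against a
whole-genome truth panel: it extracts the manifest sites, discards phase,
and applies a minor-allele-frequency floor computed on the genotype panel's
own samples (default 1 %).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthpop import MISSING, ArrayManifest, HaplotypePanel

__all__ = ["GenotypePanel", "MaskLog", "mask_to_array"]


@dataclass
class GenotypePanel:
    """Unphased diploid genotypes at typed sites.

    ``genotypes`` is (n_samples, n_sites) over {0, 1, 2} with ``MISSING``
    (-1) allowed; every retained genotype equals the truth panel's haplotype
    sum for that sample.
    """

    sites: pd.DataFrame
    genotypes: np.ndarray
    sample_ids: list[str]
    source_manifest: str = ""

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.sample_ids), len(self.sites)):
            raise ValueError("genotype matrix shape must be (n_samples, n_sites)")
        self.sites = self.sites.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_keys(self) -> pd.Index:
        s = self.sites
        return pd.Index(zip(s["contig"], s["pos"], s["ref"], s["alt"]))

    def maf(self) -> np.ndarray:
        g = self.genotypes
        obs = g != MISSING
        n_alleles = 2 * obs.sum(axis=0)
        ac = np.where(obs, g, 0).sum(axis=0)
        af = np.where(n_alleles > 0, ac / np.maximum(n_alleles, 1), 0.0)
        return np.minimum(af, 1.0 - af)


@dataclass(frozen=True)
class MaskLog:
    """Sites dropped while building the genotype panel, by reason."""

    absent_from_truth: int
    below_maf_floor: int


def mask_to_array(
    truth: HaplotypePanel,
    manifest: ArrayManifest,
    maf_floor: float = 0.01,
) -> tuple[GenotypePanel, MaskLog]:
    """Extract manifest sites from a truth panel into an unphased array panel.

    Manifest sites absent from the truth panel are dropped and counted;
    remaining sites are kept only if their MAF, computed on the genotype
    panel's own samples, is >= ``maf_floor``.  Genotypes are exactly the
    truth haplotype sums (phase discarded).
    """
    truth_keys = truth.site_keys()
    manifest_keys = manifest.site_keys()
    locs = truth_keys.get_indexer(manifest_keys)
    absent = int((locs < 0).sum())
    present = locs[locs >= 0]
    if present.size == 0:
        raise ValueError("no manifest site is present in the truth panel")

    ds = truth.diploid_dosages()[:, present]
    obs = ds != MISSING
    n_alleles = 2 * obs.sum(axis=0)
    ac = np.where(obs, ds, 0).sum(axis=0)
    af = np.where(n_alleles > 0, ac / np.maximum(n_alleles, 1), 0.0)
    maf = np.minimum(af, 1.0 - af)
    pass_floor = maf >= maf_floor
    below = int((~pass_floor).sum())

    keep = present[pass_floor]
    panel = GenotypePanel(
        sites=truth.sites.iloc[keep][["contig", "pos", "ref", "alt"]],
        genotypes=truth.diploid_dosages()[:, keep],
        sample_ids=list(truth.sample_ids),
        source_manifest=manifest.design_pop,
    )
    return panel, MaskLog(absent_from_truth=absent, below_maf_floor=below)
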