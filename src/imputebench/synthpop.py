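"""Forward-in-time simulation of diverging populations and array design.

The generator emulates the data a population-scale imputation study works
with: several cohorts of phased haplotypes descended from a common founder
pool, with tunable divergence between cohorts, a site-frequency spectrum
that contains rare variants, and linkage disequilibrium that decays along
the chromosome.  On top of the simulated panels it designs
population-optimized genotyping-array manifests by greedy tag-SNP selection,
and splits cohorts into a reference panel and a truth-bearing target set.

Model sketch
------------
A pool of ``founder_pool_haps`` haplotypes is drawn site-wise from a
Beta(0.2, 0.2)-shaped frequency spectrum.  An ancestral Wright-Fisher
population is seeded from that pool and evolved for ``mixing_generations``
(recombination breaks the founder haplotypes into blocks, drift builds LD).
Each study population is then founded from the ancestral generation and
drifts independently for ``split_generations`` generations with symmetric
per-site mutation.  All randomness flows through one seeded generator per
population, spawned from the configured seed, so output is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PopSpec",
    "SimConfig",
    "HaplotypePanel",
    "ArrayManifest",
    "ConfigError",
    "simulate_populations",
    "design_array",
    "split_reference_target",
    "inject_switch_errors",
]

MISSING = -1  # sentinel for a missing allele in haplotype/genotype matrices

_NUC = np.array(list("ACGT"))


class ConfigError(ValueError):
    """Raised for degenerate or inconsistent simulation configuration."""


@dataclass(frozen=True)
class PopSpec:
    """One study population: name, Wright-Fisher size, samples to emit."""

    name: str
    ne: int
    sample_n: int


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the multi-population haplotype simulation.

    Parameters
    ----------
    n_sites:
        Number of candidate biallelic sites on the single simulated contig.
    seq_length_cM:
        Genetic-map length in centimorgans.  Physical coordinates are laid
        out at a uniform 1 cM/Mb, so the contig spans ``seq_length_cM`` Mb.
    pops:
        Study populations (:class:`PopSpec`).
    split_generations:
        Generations of independent drift after the founder split.
    mu:
        Per-site, per-generation symmetric allele-flip probability.
    recomb_per_cM:
        Scale on the per-interval crossover probability (1.0 means one
        centimorgan is a 1 % crossover interval).
    seed:
        Master RNG seed; fixed seed implies bit-identical output.
    founder_pool_haps:
        Size of the site-wise Beta(0.2, 0.2) founder haplotype pool.
    mixing_generations:
        Shared ancestral Wright-Fisher generations before the split.
    """

    n_sites: int
    seq_length_cM: float
    pops: tuple[PopSpec, ...]
    split_generations: int
    mu: float = 1e-5
    recomb_per_cM: float = 1.0
    seed: int = 0
    founder_pool_haps: int = 96
    mixing_generations: int = 60
    contig: str = "1"

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ConfigError("n_sites must be >= 1")
        if not self.pops:
            raise ConfigError("at least one population is required")
        for p in self.pops:
            if p.ne < 2:
                raise ConfigError(f"population {p.name!r}: Ne must be >= 2")
            if p.sample_n < 1:
                raise ConfigError(f"population {p.name!r}: sample_n must be >= 1")
            if p.sample_n > p.ne:
                raise ConfigError(f"population {p.name!r}: sample_n exceeds Ne")
        if self.split_generations < 0:
            raise ConfigError("split_generations must be >= 0")
        if not (0 <= self.mu < 1):
            raise ConfigError("mu must lie in [0, 1)")
        if self.seq_length_cM <= 0:
            raise ConfigError("seq_length_cM must be positive")
        if self.founder_pool_haps < 2:
            raise ConfigError("founder_pool_haps must be >= 2")
        if self.mixing_generations < 0:
            raise ConfigError("mixing_generations must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["pops"] = tuple(
            PopSpec(p["name"], int(p["ne"]), int(p["sample_n"])) for p in d["pops"]
        )
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pops"] = [dataclasses.asdict(p) for p in self.pops]
        return d


@dataclass
class HaplotypePanel:
    """Phased biallelic haplotypes with per-site metadata.

    ``sites`` is a DataFrame with columns ``contig``, ``pos`` (0-based),
    ``ref``, ``alt``, ``af`` (non-reference allele frequency); positions are
    strictly increasing within a contig.  ``haplotypes`` is a
    ``(2 * n_samples, n_sites)`` int8 matrix over {0, 1} with ``MISSING``
    (-1) allowed for missing alleles; haplotypes ``2i`` and ``2i + 1``
    belong to sample ``i``.
    """

    sites: pd.DataFrame
    haplotypes: np.ndarray
    sample_ids: list[str]
    phased: bool = True

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D matrix")
        if self.haplotypes.shape[0] != 2 * len(self.sample_ids):
            raise ValueError("haplotype rows must be 2 * n_samples")
        if self.haplotypes.shape[1] != len(self.sites):
            raise ValueError("haplotype columns must match site count")
        self.sites = self.sites.reset_index(drop=True)
        for contig, grp in self.sites.groupby("contig", sort=False):
            if not np.all(np.diff(grp["pos"].to_numpy()) > 0):
                raise ValueError(f"positions not strictly increasing on {contig}")
        if "af" not in self.sites.columns:
            self.sites["af"] = self.recompute_af()

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def recompute_af(self) -> np.ndarray:
        """Non-reference AF per site: column mean over non-missing alleles."""
        h = self.haplotypes
        obs = h != MISSING
        n_obs = obs.sum(axis=0)
        alt = np.where(obs, h, 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            af = np.where(n_obs > 0, alt / np.maximum(n_obs, 1), 0.0)
        return af

    def maf(self) -> np.ndarray:
        af = self.sites["af"].to_numpy()
        return np.minimum(af, 1.0 - af)

    def allele_counts(self) -> np.ndarray:
        """Non-reference allele count per site over non-missing alleles."""
        h = self.haplotypes
        return np.where(h != MISSING, h, 0).sum(axis=0)

    def diploid_dosages(self) -> np.ndarray:
        """(n_samples, n_sites) genotype dosage; MISSING where either allele is."""
        h = self.haplotypes
        a, b = h[0::2], h[1::2]
        ds = (a + b).astype(np.int8)
        ds[(a == MISSING) | (b == MISSING)] = MISSING
        return ds

    def site_keys(self) -> pd.Index:
        s = self.sites
        return pd.Index(zip(s["contig"], s["pos"], s["ref"], s["alt"]))

    def subset_sites(self, idx: np.ndarray) -> "HaplotypePanel":
        idx = np.asarray(idx)
        return HaplotypePanel(
            sites=self.sites.iloc[idx].reset_index(drop=True),
            haplotypes=self.haplotypes[:, idx].copy(),
            sample_ids=list(self.sample_ids),
            phased=self.phased,
        )

    def subset_samples(self, sample_idx: np.ndarray) -> "HaplotypePanel":
        sample_idx = np.asarray(sample_idx)
        hap_idx = np.empty(2 * sample_idx.size, dtype=np.int64)
        hap_idx[0::2] = 2 * sample_idx
        hap_idx[1::2] = 2 * sample_idx + 1
        panel = HaplotypePanel(
            sites=self.sites.drop(columns="af"),
            haplotypes=self.haplotypes[hap_idx].copy(),
            sample_ids=[self.sample_ids[i] for i in sample_idx],
            phased=self.phased,
        )
        return panel


@dataclass
class ArrayManifest:
    """Ordered typed-site list defining a mimicked genotyping array.

    ``sites`` has columns ``contig``, ``pos`` (0-based), ``ref``, ``alt``;
    it is a duplicate-free, position-ordered subset of the design panel.
    """

    design_pop: str
    sites: pd.DataFrame
    target_density: int

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        keys = list(zip(self.sites["contig"], self.sites["pos"]))
        if len(keys) != len(set(keys)):
            raise ValueError("manifest contains duplicate sites")
        for _, grp in self.sites.groupby("contig", sort=False):
            if not np.all(np.diff(grp["pos"].to_numpy()) > 0):
                raise ValueError("manifest sites not ordered by position")

    def __len__(self) -> int:
        return len(self.sites)

    def site_keys(self) -> pd.Index:
        s = self.sites
        return pd.Index(zip(s["contig"], s["pos"], s["ref"], s["alt"]))


# ---------------------------------------------------------------------------
# Wright-Fisher machinery


def _interval_recomb(pos_cM: np.ndarray, recomb_per_cM: float) -> np.ndarray:
    """Per-adjacent-interval crossover probability from genetic positions."""
    d = np.diff(pos_cM)
    return np.clip(d / 100.0 * recomb_per_cM, 0.0, 0.5)


def _gametes(
    haps: np.ndarray, parents: np.ndarray, interval_r: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One recombinant gamete per entry of ``parents`` (diploid indices)."""
    n = parents.size
    n_sites = haps.shape[1]
    start = rng.integers(0, 2, size=n, dtype=np.int8)
    if n_sites > 1:
        co = (rng.random((n, n_sites - 1)) < interval_r[None, :]).astype(np.int8)
        choice = np.empty((n, n_sites), dtype=np.int8)
        choice[:, 0] = start
        choice[:, 1:] = (start[:, None] + np.cumsum(co, axis=1)) & 1
    else:
        choice = start[:, None]
    h1 = haps[2 * parents]
    h2 = haps[2 * parents + 1]
    return np.where(choice == 0, h1, h2)


def _wf_generations(
    haps: np.ndarray,
    n_out_diploid: int,
    generations: int,
    interval_r: np.ndarray,
    mu: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Evolve a Wright-Fisher population for ``generations`` generations.

    The first generation resizes the population to ``n_out_diploid``
    diploids; subsequent generations keep that size.  Mutation flips alleles
    symmetrically with probability ``mu`` per allele per generation.
    """
    cur = haps
    for _ in range(generations):
        parents = rng.integers(0, cur.shape[0] // 2, size=2 * n_out_diploid)
        cur = _gametes(cur, parents, interval_r, rng)
        if mu > 0:
            flips = rng.random(cur.shape) < mu
            cur = np.where(flips, 1 - cur, cur).astype(np.int8)
    if generations == 0 and cur.shape[0] != 2 * n_out_diploid:
        parents = rng.integers(0, cur.shape[0] // 2, size=2 * n_out_diploid)
        cur = _gametes(cur, parents, interval_r, rng)
    return cur


def simulate_populations(config: SimConfig) -> dict[str, HaplotypePanel]:
    """Simulate one phased :class:`HaplotypePanel` per configured population.

    All populations share the founder site set; divergence (e.g. Hudson Fst
    averaged over common sites) is non-decreasing in ``split_generations`` in
    expectation.  Deterministic given ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_global, *pop_seeds = ss.spawn(1 + len(config.pops))
    rng = np.random.default_rng(rng_global)

    length_bp = int(config.seq_length_cM * 1e6)
    if config.n_sites > length_bp - 1:
        raise ConfigError("n_sites exceeds available physical positions")
    pos_bp = np.sort(
        rng.choice(np.arange(1, length_bp), size=config.n_sites, replace=False)
    )
    pos_cM = pos_bp / 1e6  # uniform 1 cM/Mb map
    interval_r = _interval_recomb(pos_cM, config.recomb_per_cM)

    ref_idx = rng.integers(0, 4, size=config.n_sites)
    alt_off = rng.integers(1, 4, size=config.n_sites)
    ref = _NUC[ref_idx]
    alt = _NUC[(ref_idx + alt_off) % 4]

    founder_freq = rng.beta(0.2, 0.2, size=config.n_sites)
    founders = (
        rng.random((config.founder_pool_haps, config.n_sites)) < founder_freq[None, :]
    ).astype(np.int8)

    ne_anc = max(p.ne for p in config.pops)
    ancestral = _wf_generations(
        founders, ne_anc, max(config.mixing_generations, 1), interval_r, config.mu, rng
    )

    panels: dict[str, HaplotypePanel] = {}
    for pop, seed_seq in zip(config.pops, pop_seeds):
        prng = np.random.default_rng(seed_seq)
        pop_haps = _wf_generations(
            ancestral, pop.ne, max(config.split_generations, 1), interval_r, config.mu, prng
        )
        keep = prng.choice(pop.ne, size=pop.sample_n, replace=False)
        keep.sort()
        hap_idx = np.empty(2 * keep.size, dtype=np.int64)
        hap_idx[0::2] = 2 * keep
        hap_idx[1::2] = 2 * keep + 1
        sites = pd.DataFrame(
            {"contig": config.contig, "pos": pos_bp, "ref": ref, "alt": alt}
        )
        panels[pop.name] = HaplotypePanel(
            sites=sites,
            haplotypes=pop_haps[hap_idx],
            sample_ids=[f"{pop.name}_{i:04d}" for i in range(pop.sample_n)],
            phased=True,
        )
    return panels


# ---------------------------------------------------------------------------
# Array design


def design_array(
    panel: HaplotypePanel,
    target_density: int,
    maf_floor: float = 0.05,
    ld_r2_tag: float = 0.8,
    design_pop: str = "design",
) -> ArrayManifest:
    """Design a population-optimized array manifest by greedy tag selection.

    Candidate sites are those with MAF >= ``maf_floor`` in the design panel.
    The greedy step repeatedly picks the candidate covering the most not-yet
    -covered common sites at r^2 >= ``ld_r2_tag`` (a site covers itself);
    ties break toward the lower position.  Selection stops at
    ``target_density`` sites or when no pick adds coverage, so the manifest
    may be smaller than requested.
    """
    if not (0 < maf_floor < 0.5):
        raise ValueError("maf_floor must lie in (0, 0.5)")
    maf = panel.maf()
    cand = np.flatnonzero(maf >= maf_floor)
    if cand.size == 0:
        raise ValueError("no site passes the MAF floor in the design population")
    if target_density > cand.size:
        raise ValueError(
            f"target_density {target_density} exceeds {cand.size} sites passing the MAF floor"
        )

    h = panel.haplotypes[:, cand].astype(np.float64)
    r = np.corrcoef(h, rowvar=False)
    if r.ndim == 0:  # single candidate
        r = np.array([[1.0]])
    cover = (r * r) >= ld_r2_tag

    covered = np.zeros(cand.size, dtype=bool)
    available = np.ones(cand.size, dtype=bool)
    picked: list[int] = []
    for _ in range(target_density):
        gains = cover[:, ~covered].sum(axis=1)
        gains[~available] = -1
        best_gain = gains.max()
        if best_gain <= 0:
            break
        best = int(np.flatnonzero(gains == best_gain)[0])  # candidates position-sorted
        picked.append(best)
        covered |= cover[best]
        available[best] = False

    idx = np.sort(cand[np.array(picked, dtype=np.int64)])
    sites = panel.sites.iloc[idx][["contig", "pos", "ref", "alt"]]
    return ArrayManifest(design_pop=design_pop, sites=sites, target_density=target_density)


def split_reference_target(
    panel: HaplotypePanel, n_target: int, seed: int
) -> tuple[HaplotypePanel, HaplotypePanel]:
    """Partition samples into a reference panel and a disjoint target set."""
    if n_target >= panel.n_samples:
        raise ValueError("n_target must be smaller than the number of samples")
    if n_target < 1:
        raise ValueError("n_target must be >= 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(panel.n_samples)
    target_idx = np.sort(perm[:n_target])
    ref_idx = np.sort(perm[n_target:])
    return panel.subset_samples(ref_idx), panel.subset_samples(target_idx)


def inject_switch_errors(
    panel: HaplotypePanel, switch_rate: float, seed: int
) -> HaplotypePanel:
    """Perturb phase with per-heterozygote switch errors.

    Walking each sample left to right, the phase orientation toggles at each
    heterozygous site with probability ``switch_rate``; while toggled, the
    two alleles of the sample are swapped.  Diploid genotypes are unchanged
    by construction.
    """
    if not (0.0 <= switch_rate <= 1.0):
        raise ValueError("switch_rate must lie in [0, 1]")
    if not panel.phased:
        raise ValueError("panel must be phased")
    rng = np.random.default_rng(seed)
    h = panel.haplotypes.copy()
    a, b = h[0::2], h[1::2]
    het = a != b
    toggles = het & (rng.random(het.shape) < switch_rate)
    state = np.cumsum(toggles, axis=1) & 1  # 1 => swapped orientation
    swap = (state == 1)
    a_new = np.where(swap, b, a)
    b_new = np.where(swap, a, b)
    h[0::2] = a_new
    h[1::2] = b_new
    return HaplotypePanel(
        sites=panel.sites.drop(columns="af"),
        haplotypes=h,
        sample_ids=list(panel.sample_ids),
        phased=True,
    )
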