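"""The standard two-population benchmark scenario.

A desk-scale analogue of a population-scale imputation study: two cohorts
("POPA", "POPB") of 150 samples each, Wright-Fisher size 500, diverged for
200 generations after 120 generations of shared ancestral mixing, over 800
candidate sites on a 4 cM segment.  Per cohort, 100 samples form the
reference panel (after QC) and 50 are held out as the truth-bearing target
set.  One array is designed per population (greedy tag selection, 30 typed
sites — sparse relative to the segregating sites, as real arrays are
relative to panel variants), targets of POPA are masked to each array,
imputed against both reference panels, meta-imputed across them, and
scored per allele-frequency bin against the held-out truth.

Two experiments are defined on these cohorts:

* the panel/array contrast (:func:`run_benchmark`) — sparse arrays of 30
  typed sites (mirroring how sparse real arrays are relative to the
  variants of a sequencing panel) stress content ascertainment.  Each
  panel x array combination is scored on its own imputed sites
  (``single``) and, for ranking the four combinations like for like, on
  sites typed on neither array (``array_rank``), which removes the
  asymmetry that a combination never scores its own typed sites;
* the meta-imputation experiment (:func:`run_meta_benchmark`) — a denser
  typed backbone of 80 sites (per-Mb typed density closer to a real
  array) gives the panel-selection HMM the evidence it needs; accuracy is
  compared on the site set shared by both panels (``shared``) while
  variant yield (``n_well_imputed``) is compared on the full outputs,
  where the union of panel sites is the point.

These sizes are the package's standard study conditions; the helpers here
are consumed by the examples, the test suite and the reproduction script
so all of them measure the same experiment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arraymask import mask_to_array
from .evalmetrics import AFBinSpec, EvalReport, evaluate
from .lsimpute import DosageSet, LSParams, impute
from .metaimpute import MetaParams, meta_combine
from .panelqc import QCThresholds, apply_qc_cascade
from .synthpop import (
    HaplotypePanel,
    PopSpec,
    SimConfig,
    design_array,
    simulate_populations,
    split_reference_target,
)

__all__ = [
    "BenchmarkResult",
    "MetaBenchmarkResult",
    "standard_sim_config",
    "run_benchmark",
    "run_meta_benchmark",
    "common_bin_mean_r2",
]

N_SITES = 800
SEQ_CM = 4.0
NE = 500
N_PER_POP = 150
N_TARGET = 50
SPLIT_GENERATIONS = 200
MIXING_GENERATIONS = 120
ARRAY_DENSITY = 30
META_ARRAY_DENSITY = 80


def standard_sim_config(
    seed: int,
    split_generations: int = SPLIT_GENERATIONS,
    ne: int = NE,
) -> SimConfig:
    """Two-population :class:`SimConfig` under the standard conditions."""
    return SimConfig(
        n_sites=N_SITES,
        seq_length_cM=SEQ_CM,
        pops=(PopSpec("POPA", ne, N_PER_POP), PopSpec("POPB", ne, N_PER_POP)),
        split_generations=split_generations,
        mixing_generations=MIXING_GENERATIONS,
        seed=seed,
    )


@dataclass
class BenchmarkResult:
    """One seed's panel/array contrast for target cohort POPA.

    ``single`` and ``array_rank`` map (ref_pop, array_pop) combinations to
    :class:`EvalReport` objects under the protocols described in the
    module docstring.
    """

    single: dict[tuple[str, str], EvalReport]
    array_rank: dict[tuple[str, str], EvalReport]


@dataclass
class MetaBenchmarkResult:
    """One seed's meta-imputation experiment for target cohort POPA.

    ``shared`` holds reports on the site set shared by both panels, keyed
    "POPA", "POPB", "meta"; ``n_well_imputed`` counts sites at estimated
    r^2 >= 0.8 over each full output (union sites for meta).
    """

    shared: dict[str, EvalReport]
    full: dict[str, EvalReport]
    n_well_imputed: dict[str, int]


def _split_and_qc(
    panels: dict[str, HaplotypePanel], seed: int
) -> tuple[dict[str, HaplotypePanel], dict[str, HaplotypePanel]]:
    thresholds = QCThresholds(min_external_datasets=0)
    refs: dict[str, HaplotypePanel] = {}
    truths: dict[str, HaplotypePanel] = {}
    for i, name in enumerate(["POPA", "POPB"]):
        ref, tgt = split_reference_target(panels[name], N_TARGET, seed=seed + 1000 + i)
        refs[name], _ = apply_qc_cascade(ref, thresholds=thresholds)
        truths[name] = tgt
    return refs, truths


def _typed_targets(truth: HaplotypePanel, array) -> HaplotypePanel:
    geno, _ = mask_to_array(truth, array)
    return truth.subset_sites(truth.site_keys().get_indexer(geno.site_keys()))


def run_benchmark(seed: int, bins: AFBinSpec = AFBinSpec()) -> BenchmarkResult:
    """Panel/array contrast: score all four panel x array combinations."""
    panels = simulate_populations(standard_sim_config(seed))
    refs, truths = _split_and_qc(panels, seed)
    arrays = {
        name: design_array(refs[name], ARRAY_DENSITY, design_pop=name)
        for name in ["POPA", "POPB"]
    }
    truth = truths["POPA"]
    array_union = arrays["POPA"].site_keys().union(arrays["POPB"].site_keys())
    single: dict[tuple[str, str], EvalReport] = {}
    array_rank: dict[tuple[str, str], EvalReport] = {}
    for aname in ["POPA", "POPB"]:
        typed = _typed_targets(truth, arrays[aname])
        for rname in ["POPA", "POPB"]:
            dos, _ = impute(typed, refs[rname], LSParams(), panel_id=rname)
            single[(rname, aname)] = evaluate(dos, truth, bins)
            neutral = dos.site_keys().difference(array_union)
            array_rank[(rname, aname)] = evaluate(dos.restrict(neutral), truth, bins)
    return BenchmarkResult(single=single, array_rank=array_rank)


def run_meta_benchmark(seed: int, bins: AFBinSpec = AFBinSpec()) -> MetaBenchmarkResult:
    """Meta-imputation experiment: combine both panels on the matched array."""
    panels = simulate_populations(standard_sim_config(seed))
    refs, truths = _split_and_qc(panels, seed)
    truth = truths["POPA"]
    array = design_array(refs["POPA"], META_ARRAY_DENSITY, design_pop="POPA")
    typed = _typed_targets(truth, array)
    dosages: dict[str, DosageSet] = {
        name: impute(typed, refs[name], LSParams(), panel_id=name)[0]
        for name in ["POPA", "POPB"]
    }
    meta_dos = meta_combine([dosages["POPA"], dosages["POPB"]], typed, MetaParams())

    full = {name: evaluate(d, truth, bins) for name, d in dosages.items()}
    full["meta"] = evaluate(meta_dos, truth, bins)
    shared_keys = dosages["POPA"].site_keys().intersection(dosages["POPB"].site_keys())
    shared = {
        name: evaluate(d.restrict(shared_keys), truth, bins)
        for name, d in dosages.items()
    }
    shared["meta"] = evaluate(meta_dos.restrict(shared_keys), truth, bins)
    n_well = {name: int(rep.table["n_well_imputed"].sum()) for name, rep in full.items()}
    return MetaBenchmarkResult(shared=shared, full=full, n_well_imputed=n_well)


def common_bin_mean_r2(report: EvalReport) -> float:
    """Mean aggregated R^2 in the common (>= 5 % AF) bin."""
    return float(report.table["mean_r2"].iloc[-1])


def founder_panel(seed: int, n_sites: int = N_SITES, n_samples: int = N_PER_POP) -> HaplotypePanel:
    """Panel of site-wise independent haplotypes (Beta(0.2, 0.2) spectrum).

    Every haplotype is distinct with overwhelming probability, so a target
    haplotype drawn from the panel is uniquely identified by its typed
    alleles — the setting in which the copying model must recover untyped
    alleles essentially exactly.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    freq = rng.beta(0.2, 0.2, n_sites)
    haps = (rng.random((2 * n_samples, n_sites)) < freq).astype(np.int8)
    pos = np.sort(rng.choice(np.arange(1, 2_000_000), n_sites, replace=False))
    sites = pd.DataFrame({"contig": "1", "pos": pos, "ref": "A", "alt": "G"})
    return HaplotypePanel(
        sites=sites, haplotypes=haps, sample_ids=[f"S{i}" for i in range(n_samples)]
    )


def run_recovery_check(seed: int, n_targets: int = 30, typed_step: int = 3):
    """Impute targets copied from the panel itself (near-zero mismatch rate).

    Returns the per-bin evaluation report; with a distinct-haplotype panel
    the mean aggregated R^2 is expected to be ~1 in every populated bin.
    """
    ref = founder_panel(seed)
    truth = ref.subset_samples(np.arange(n_targets))
    typed = truth.subset_sites(np.arange(0, ref.n_sites, typed_step))
    dos, _ = impute(typed, ref, LSParams(err=1e-8), panel_id="self")
    return evaluate(dos, truth, AFBinSpec())


# ---------------------------------------------------------------------------
# varLD experiments: null calibration and a planted LD-destroyed window

VARLD_N_SITES = 1500
VARLD_SEQ_CM = 3.0
VARLD_NE = 300
VARLD_SAMPLES = 100
VARLD_CONFIG_KW = dict(window_size=20, step=3)
PLANT_SPAN_SITES = 30


def _varld_population(seed: int) -> HaplotypePanel:
    cfg = SimConfig(
        n_sites=VARLD_N_SITES,
        seq_length_cM=VARLD_SEQ_CM,
        pops=(PopSpec("P", VARLD_NE, VARLD_SAMPLES),),
        split_generations=50,
        mixing_generations=80,
        seed=seed,
    )
    return simulate_populations(cfg)["P"]


def _halves(panel: HaplotypePanel) -> tuple[HaplotypePanel, HaplotypePanel]:
    import numpy as np

    half = panel.n_samples // 2
    return panel.subset_samples(np.arange(half)), panel.subset_samples(
        np.arange(half, panel.n_samples)
    )


def run_varld_null(seed: int) -> tuple[int, int]:
    """Self-comparison of two disjoint halves of one cohort.

    Returns (n_windows, n_called_windows): windows whose standardized score
    exceeds the top-1 % nearest-rank cutoff.  Under the null the strict-
    exceedance rule caps calls at 1 % of windows by construction; the
    experiment verifies the scan produces no pathological excess.
    """
    import math

    import numpy as np

    from .varld import VarLDConfig, varld_scan

    a, b = _halves(_varld_population(seed))
    windows, _ = varld_scan(a, b, VarLDConfig(**VARLD_CONFIG_KW))
    z = np.array([w.standardized for w in windows])
    n = len(z)
    rank = max(1, math.ceil(0.99 * n))
    cutoff = np.sort(z)[rank - 1]
    return n, int((z > cutoff).sum())


def run_varld_planted(seed: int) -> bool:
    """Destroy LD in one half within a span of common sites; detect it?

    Within the planted span each site's alleles are independently permuted
    across haplotypes (allele frequencies preserved, LD destroyed).  Returns
    True when a called top-1 % region overlaps the planted span.
    """
    import numpy as np

    from .varld import VarLDConfig, varld_scan

    panel = _varld_population(seed)
    a, b = _halves(panel)
    maf_a, maf_b = a.maf(), b.maf()
    common = np.flatnonzero((maf_a >= 0.05) & (maf_b >= 0.05))
    mid = len(common) // 2
    span = common[mid : mid + PLANT_SPAN_SITES]
    haps = b.haplotypes.copy()
    rng = np.random.default_rng(seed)
    for j in span:
        haps[:, j] = haps[rng.permutation(haps.shape[0]), j]
    planted = HaplotypePanel(
        sites=b.sites.drop(columns="af"),
        haplotypes=haps,
        sample_ids=list(b.sample_ids),
        phased=True,
    )
    _, regions = varld_scan(a, planted, VarLDConfig(**VARLD_CONFIG_KW))
    pos = a.sites["pos"].to_numpy()
    s_start, s_end = int(pos[span[0]]), int(pos[span[-1]]) + 1
    return any(
        (r.start < s_end and r.end > s_start) for r in regions.itertuples(index=False)
    )
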