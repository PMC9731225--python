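"""Meta-imputation: combining dosages from several reference panels.

When the same target cohort is imputed against multiple reference panels,
the panels' relative accuracy varies along the genome with local haplotype
sharing.  The combiner models, per target haplotype, a hidden "generating
panel" that switches along the chromosome: at each typed site the emission
likelihood of panel *k* is its leave-one-out dosage if the observed allele
is the alternative allele and one minus it otherwise, so panels whose
blinded typed-site predictions track the observed alleles gain weight.
Forward-backward posteriors over panels become per-haplotype weights,
linearly interpolated between typed sites, and the meta dosage is the
weighted sum of the panel dosages (weights renormalized over the panels
that carry a site).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lsimpute import DosageSet, _est_r2_columns
from .synthpop import MISSING, HaplotypePanel

__all__ = ["MetaParams", "MetaWeights", "panel_weight_hmm", "meta_combine"]


@dataclass(frozen=True)
class MetaParams:
    """Combiner parameters: per-typed-interval panel-switch probability and
    the floor applied to emission likelihoods (keeps zero-dosage panels from
    collapsing the forward pass)."""

    switch_prob: float = 0.01
    weight_floor: float = 1e-6

    def __post_init__(self) -> None:
        if not (0.0 < self.switch_prob < 1.0):
            raise ValueError("switch_prob must lie in (0, 1)")
        if not (0.0 < self.weight_floor < 1.0):
            raise ValueError("weight_floor must lie in (0, 1)")


@dataclass
class MetaWeights:
    """Per (target haplotype, typed site, panel) weights; rows sum to 1."""

    weights: np.ndarray  # (n_haps, n_typed, n_panels)
    panel_ids: list[str]

    def __post_init__(self) -> None:
        sums = self.weights.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("weights must sum to 1 over panels")


def _weight_fb(
    emit: np.ndarray, switch_prob: float
) -> np.ndarray:
    """Forward-backward over panels; ``emit`` is (n_haps, n_sites, K)."""
    n_t, n_s, k = emit.shape
    q = switch_prob / (k - 1)
    stay = 1.0 - switch_prob

    fwd = np.empty_like(emit)
    f = np.full((n_t, k), 1.0 / k) * emit[:, 0, :]
    f /= f.sum(axis=1, keepdims=True)
    fwd[:, 0, :] = f
    for s in range(1, n_s):
        a = (stay - q) * f + q  # f sums to 1
        f = a * emit[:, s, :]
        f /= f.sum(axis=1, keepdims=True)
        fwd[:, s, :] = f

    b = np.full((n_t, k), 1.0)
    gamma = np.empty_like(emit)
    gamma[:, -1, :] = fwd[:, -1, :]
    for s in range(n_s - 2, -1, -1):
        eb = emit[:, s + 1, :] * b
        b = (stay - q) * eb + q * eb.sum(axis=1, keepdims=True)
        b /= b.sum(axis=1, keepdims=True)
        gamma[:, s, :] = fwd[:, s, :] * b
    gamma /= gamma.sum(axis=2, keepdims=True)
    return gamma


def panel_weight_hmm(
    observed_alleles: np.ndarray,
    loo_per_panel: list[np.ndarray],
    params: MetaParams = MetaParams(),
) -> MetaWeights:
    """Panel-selection posteriors for one target haplotype.

    ``observed_alleles`` are the haplotype's typed alleles in {0, 1}
    (``MISSING`` treated as uninformative); ``loo_per_panel`` holds each
    panel's leave-one-out dosages aligned to the same typed sites.
    """
    if len(loo_per_panel) < 2:
        raise ValueError("at least two panels are required")
    obs = np.asarray(observed_alleles)
    if obs.size == 0:
        raise ValueError("empty typed-site intersection")
    loo = np.stack([np.asarray(v, dtype=np.float64) for v in loo_per_panel], axis=-1)
    if loo.shape[0] != obs.size:
        raise ValueError("leave-one-out vectors must align with observed alleles")
    emit = np.where(obs[:, None] == 1, loo, 1.0 - loo)
    emit = np.maximum(emit, params.weight_floor)
    emit[obs == MISSING] = 1.0
    gamma = _weight_fb(emit[None, :, :], params.switch_prob)[0]
    return MetaWeights(weights=gamma[None, :, :], panel_ids=[str(i) for i in range(loo.shape[1])])


def meta_combine(
    dosage_sets: list[DosageSet],
    targets_typed: HaplotypePanel,
    params: MetaParams = MetaParams(),
) -> DosageSet:
    """Combine per-panel dosages into one meta-imputed :class:`DosageSet`.

    Weights come from the panel-selection HMM run on the typed-site
    intersection of all panels; at other sites they are linearly
    interpolated in position between flanking typed sites (held constant
    beyond the outermost ones) and renormalized over the panels that carry
    the site.  The output covers the union of the panels' sites; its
    estimated r^2 is recomputed from the meta haplotype dosages.
    """
    if len(dosage_sets) < 2:
        raise ValueError("at least two dosage sets are required")
    samples = dosage_sets[0].sample_ids
    for d in dosage_sets[1:]:
        if d.sample_ids != samples:
            raise ValueError("dosage sets come from different target cohorts")
    k = len(dosage_sets)
    n_haps = 2 * len(samples)

    # typed intersection across panels, restricted to sites the targets carry
    typed_keys = dosage_sets[0].site_keys()[dosage_sets[0].typed_idx]
    for d in dosage_sets[1:]:
        typed_keys = typed_keys.intersection(d.site_keys()[d.typed_idx])
    typed_keys = typed_keys.intersection(targets_typed.site_keys())
    if len(typed_keys) == 0:
        raise ValueError("empty typed-site intersection across panels")
    typed_df = pd.DataFrame(list(typed_keys), columns=["contig", "pos", "ref", "alt"])
    typed_df = typed_df.sort_values(["contig", "pos"]).reset_index(drop=True)
    typed_keys = pd.Index(zip(typed_df["contig"], typed_df["pos"], typed_df["ref"], typed_df["alt"]))

    obs = targets_typed.haplotypes[:, targets_typed.site_keys().get_indexer(typed_keys)]
    loo_stack = np.empty((n_haps, len(typed_keys), k))
    for i, d in enumerate(dosage_sets):
        panel_typed_keys = d.site_keys()[d.typed_idx]
        cols = pd.Index(panel_typed_keys).get_indexer(typed_keys)
        loo_stack[:, :, i] = d.loo[:, cols]

    emit = np.where(obs[:, :, None] == 1, loo_stack, 1.0 - loo_stack)
    emit = np.maximum(emit, params.weight_floor)
    emit[obs == MISSING] = 1.0
    w_typed = _weight_fb(emit, params.switch_prob)  # (n_haps, T, K)

    # union of panel sites, position-ordered
    union = dosage_sets[0].sites[["contig", "pos", "ref", "alt"]]
    for d in dosage_sets[1:]:
        union = pd.concat([union, d.sites[["contig", "pos", "ref", "alt"]]])
    union = union.drop_duplicates().sort_values(["contig", "pos", "ref", "alt"]).reset_index(drop=True)
    union_keys = pd.Index(zip(union["contig"], union["pos"], union["ref"], union["alt"]))
    n_union = len(union)

    typed_pos = typed_df["pos"].to_numpy(dtype=np.float64)
    pos_u = union["pos"].to_numpy(dtype=np.float64)
    right = np.clip(np.searchsorted(typed_pos, pos_u), 0, len(typed_pos) - 1)
    left = np.clip(right - 1, 0, len(typed_pos) - 1)
    span = typed_pos[right] - typed_pos[left]
    at_or_right = typed_pos[right] >= pos_u
    with np.errstate(invalid="ignore", divide="ignore"):
        w_l = np.where(span > 0, (typed_pos[right] - pos_u) / np.where(span > 0, span, 1.0), 1.0)
    w_l = np.clip(np.where(at_or_right, w_l, 0.0), 0.0, 1.0)

    # interpolated weights at every union site
    w_all = (
        w_l[None, :, None] * w_typed[:, left, :]
        + (1.0 - w_l)[None, :, None] * w_typed[:, right, :]
    )

    avail = np.zeros((k, n_union), dtype=bool)
    hds_aligned = np.zeros((k, n_haps, n_union))
    typed_union = np.zeros(n_union, dtype=bool)
    af_union = np.full(n_union, np.nan)
    for i, d in enumerate(dosage_sets):
        cols = union_keys.get_indexer(d.site_keys())
        avail[i, cols] = True
        hds_aligned[i][:, cols] = d.hds
        typed_union[cols] |= d.typed
        af_union[cols] = d.sites["af"].to_numpy()

    w_eff = w_all * avail.T[None, :, :]
    norm = w_eff.sum(axis=2, keepdims=True)
    w_eff = np.where(norm > 0, w_eff / np.where(norm > 0, norm, 1.0), 0.0)

    meta_hds = np.einsum("nuk,knu->nu", w_eff, hds_aligned)
    meta_hds = np.clip(meta_hds, 0.0, 1.0)

    typed_idx_union = union_keys.get_indexer(typed_keys)
    meta_loo = np.clip(np.einsum("ntk,ntk->nt", w_typed, loo_stack), 0.0, 1.0)

    sites = union.copy()
    sites["typed"] = False
    sites.loc[typed_idx_union, "typed"] = True
    sites["af"] = af_union
    return DosageSet(
        sites=sites,
        hds=meta_hds,
        loo=meta_loo,
        typed_idx=np.asarray(typed_idx_union),
        est_r2=_est_r2_columns(meta_hds),
        sample_ids=list(samples),
        panel_id="meta(" + "+".join(d.panel_id or "?" for d in dosage_sets) + ")",
    )
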