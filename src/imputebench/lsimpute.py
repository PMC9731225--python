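"""Li-Stephens haplotype-copying imputation.

Each target haplotype is modelled as an imperfect mosaic of the reference
haplotypes: a hidden Markov model whose state is the reference haplotype
being copied, whose transitions are recombination-driven switches with
per-interval probability ``1 - exp(-4 * n_eff * d / H)`` spread uniformly
over the ``H`` reference haplotypes (``d`` in Morgans), and whose emissions
allow allele mismatch with probability ``err``.  A scaled forward-backward
pass yields per-site copying posteriors; dosages at untyped sites are the
posterior-weighted reference alleles with Minimac-style linear interpolation
of the flanking typed-site posteriors.  Leave-one-out dosages at typed
sites — the accuracy signal consumed by meta-imputation — are computed from
posteriors that exclude the site's own emission.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthpop import MISSING, HaplotypePanel

__all__ = ["LSParams", "DosageSet", "ls_forward_backward", "impute", "estimated_r2"]

#: genetic map assumed when only physical positions are known: 1 cM / Mb
_MORGANS_PER_BP = 1e-8


@dataclass(frozen=True)
class LSParams:
    """Copying-model parameters.

    ``n_eff`` scales recombination (effective population size), ``err`` is
    the allele-mismatch emission probability, ``min_recomb`` floors the
    per-interval switch probability so fully linked intervals stay ergodic.
    """

    n_eff: float = 1e4
    err: float = 1e-3
    min_recomb: float = 1e-8

    def __post_init__(self) -> None:
        if not (0.0 < self.err < 0.5):
            raise ValueError("err must lie in (0, 0.5)")
        if self.n_eff <= 0:
            raise ValueError("n_eff must be positive")
        if not (0.0 <= self.min_recomb < 1.0):
            raise ValueError("min_recomb must lie in [0, 1)")


@dataclass
class DosageSet:
    """Imputed dosages for a target cohort against one reference panel.

    ``hds`` holds per-haplotype alt-allele dosages in [0, 1] for every
    (target haplotype, site); ``typed`` flags sites observed on the array;
    ``loo`` holds leave-one-out haplotype dosages at the typed sites only
    (columns follow ``typed_idx``); ``est_r2`` is the per-site estimated
    imputation r^2.
    """

    sites: pd.DataFrame  # contig, pos, ref, alt, typed, af
    hds: np.ndarray  # (2 n_samples, n_sites)
    loo: np.ndarray  # (2 n_samples, n_typed)
    typed_idx: np.ndarray  # indices of typed sites into `sites`
    est_r2: np.ndarray  # (n_sites,)
    sample_ids: list[str]
    panel_id: str = ""

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        if self.hds.shape != (2 * len(self.sample_ids), len(self.sites)):
            raise ValueError("hds shape must be (2 n_samples, n_sites)")
        if self.loo.shape != (self.hds.shape[0], len(self.typed_idx)):
            raise ValueError("loo shape must be (2 n_samples, n_typed)")

    @property
    def ds(self) -> np.ndarray:
        """Diploid dosages in [0, 2]: sum of the two haplotype dosages."""
        return self.hds[0::2] + self.hds[1::2]

    @property
    def typed(self) -> np.ndarray:
        mask = np.zeros(len(self.sites), dtype=bool)
        mask[self.typed_idx] = True
        return mask

    def site_keys(self) -> pd.Index:
        s = self.sites
        return pd.Index(zip(s["contig"], s["pos"], s["ref"], s["alt"]))

    def restrict(self, keys: pd.Index) -> "DosageSet":
        """Subset to the sites in ``keys`` (e.g. a shared site set, for a
        like-for-like accuracy comparison across panels)."""
        mask = self.site_keys().isin(keys)
        idx = np.flatnonzero(mask)
        old_typed = {j: t for t, j in enumerate(self.typed_idx)}
        new_typed_idx = []
        loo_cols = []
        for new_j, j in enumerate(idx):
            if j in old_typed:
                new_typed_idx.append(new_j)
                loo_cols.append(old_typed[j])
        return DosageSet(
            sites=self.sites.iloc[idx].reset_index(drop=True),
            hds=self.hds[:, idx].copy(),
            loo=self.loo[:, loo_cols].copy(),
            typed_idx=np.asarray(new_typed_idx, dtype=np.int64),
            est_r2=self.est_r2[idx].copy(),
            sample_ids=list(self.sample_ids),
            panel_id=self.panel_id,
        )


def estimated_r2(hds_at_site: np.ndarray) -> float:
    """Minimac-style estimated imputation r^2 from haplotype dosages.

    ``Var(hds) / (p (1 - p))`` with ``p = mean(hds)`` and the population
    (divisor ``n``) variance, clamped to [0, 1]; 0 when ``p`` is 0 or 1.
    """
    h = np.asarray(hds_at_site, dtype=np.float64)
    if h.size < 2:
        raise ValueError("at least two haplotype dosages are required")
    p = h.mean()
    denom = p * (1.0 - p)
    if denom <= 0.0:
        return 0.0
    return float(np.clip(h.var() / denom, 0.0, 1.0))


def _est_r2_columns(hds: np.ndarray) -> np.ndarray:
    """Vectorized :func:`estimated_r2` over the columns of ``hds``."""
    p = hds.mean(axis=0)
    denom = p * (1.0 - p)
    var = hds.var(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(denom > 0, var / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(r2, 0.0, 1.0)


def _switch_probs(
    pos_morgans: np.ndarray, n_haps: int, params: LSParams
) -> np.ndarray:
    d = np.diff(pos_morgans)
    rho = 1.0 - np.exp(-4.0 * params.n_eff * d / n_haps)
    return np.clip(rho, params.min_recomb, 1.0 - 1e-12)


def _fb_batch(
    obs: np.ndarray,
    ref: np.ndarray,
    rho: np.ndarray,
    err: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Scaled forward-backward over a batch of target haplotypes.

    Parameters
    ----------
    obs:
        (n_targets, n_sites) observed alleles in {0, 1}, ``MISSING`` allowed
        (treated as uninformative).
    ref:
        (H, n_sites) reference alleles in {0, 1}.
    rho:
        (n_sites - 1,) per-interval switch probabilities.

    Returns
    -------
    gamma:
        (n_targets, n_sites, H) copying posteriors, rows summing to 1.
    gamma_loo:
        Same shape; the posterior at each site excluding that site's own
        emission (leave-one-out).
    """
    n_t, n_s = obs.shape
    n_h = ref.shape[0]
    if n_h < 1:
        raise ValueError("at least one reference haplotype is required")

    # emission[t, s, h] = 1-err if obs matches ref else err; 1 if obs missing
    match = obs[:, :, None] == ref.T[None, :, :]
    emit = np.where(match, 1.0 - err, err)
    emit[obs == MISSING] = 1.0

    fwd = np.empty((n_t, n_s, n_h))
    alpha = np.empty_like(fwd)  # pre-emission forward (for leave-one-out)
    alpha[:, 0, :] = 1.0 / n_h
    f = alpha[:, 0, :] * emit[:, 0, :]
    f /= f.sum(axis=1, keepdims=True)
    fwd[:, 0, :] = f
    for s in range(1, n_s):
        a = (1.0 - rho[s - 1]) * f + rho[s - 1] / n_h  # f sums to 1
        alpha[:, s, :] = a
        f = a * emit[:, s, :]
        f /= f.sum(axis=1, keepdims=True)
        fwd[:, s, :] = f

    bwd = np.empty_like(fwd)
    b = np.full((n_t, n_h), 1.0 / n_h)
    bwd[:, -1, :] = b
    for s in range(n_s - 2, -1, -1):
        eb = emit[:, s + 1, :] * b
        b = (1.0 - rho[s]) * eb + rho[s] * eb.mean(axis=1, keepdims=True)
        b /= b.sum(axis=1, keepdims=True)
        bwd[:, s, :] = b

    gamma = fwd * bwd
    gamma /= gamma.sum(axis=2, keepdims=True)
    gamma_loo = alpha * bwd
    gamma_loo /= gamma_loo.sum(axis=2, keepdims=True)
    return gamma, gamma_loo


def ls_forward_backward(
    target_hap: np.ndarray,
    ref: HaplotypePanel | np.ndarray,
    params: LSParams = LSParams(),
    pos_morgans: np.ndarray | None = None,
) -> np.ndarray:
    """Copying posteriors for one target haplotype at its typed sites.

    ``ref`` is a phased panel (or raw (H, n_sites) allele matrix) restricted
    to the typed sites.  ``pos_morgans`` gives the genetic position of each
    typed site; with physical positions a uniform 1 cM/Mb map is assumed,
    and with neither a unit-spaced 1 cM grid is used.  Rows of the returned
    (n_sites, H) matrix sum to 1.
    """
    target_hap = np.asarray(target_hap)
    if isinstance(ref, HaplotypePanel):
        ref_mat = ref.haplotypes
        if pos_morgans is None:
            pos_morgans = ref.sites["pos"].to_numpy() * _MORGANS_PER_BP
    else:
        ref_mat = np.asarray(ref)
    if ref_mat.shape[0] < 1:
        raise ValueError("reference panel has no haplotypes")
    if target_hap.size < 1:
        raise ValueError("at least one typed site is required")
    if pos_morgans is None:
        pos_morgans = np.arange(target_hap.size) * 0.01
    rho = _switch_probs(np.asarray(pos_morgans, dtype=np.float64), ref_mat.shape[0], params)
    gamma, _ = _fb_batch(target_hap[None, :], ref_mat, rho, params.err)
    return gamma[0]


@dataclass(frozen=True)
class ImputeLog:
    """Typed sites dropped because the reference panel lacks them."""

    typed_sites_absent_from_ref: int


def impute(
    targets: HaplotypePanel,
    ref: HaplotypePanel,
    params: LSParams = LSParams(),
    panel_id: str = "",
    _batch: int = 64,
) -> tuple[DosageSet, ImputeLog]:
    """Impute all reference-panel sites for a phased, typed target cohort.

    ``targets`` carries the array-typed sites only (phased); ``ref`` is the
    phased reference panel over all sites.  Typed sites absent from the
    reference are dropped with a logged count.  Dosages at untyped sites are
    posterior-weighted reference alleles, linearly interpolated in genetic
    position between flanking typed sites (nearest posterior beyond the
    outermost typed sites).  Deterministic.
    """
    if not targets.phased:
        raise ValueError("targets must be phased")
    ref_keys = ref.site_keys()
    locs = ref_keys.get_indexer(targets.site_keys())
    dropped = int((locs < 0).sum())
    typed_target_cols = np.flatnonzero(locs >= 0)
    typed_ref_idx = locs[locs >= 0]
    if typed_ref_idx.size == 0:
        raise ValueError("no overlap between typed sites and the reference panel")
    order = np.argsort(typed_ref_idx)
    typed_ref_idx = typed_ref_idx[order]
    typed_target_cols = typed_target_cols[order]

    obs_all = targets.haplotypes[:, typed_target_cols]
    ref_typed = ref.haplotypes[:, typed_ref_idx]
    ref_all = ref.haplotypes.astype(np.float64)
    n_h_ref = ref.haplotypes.shape[0]

    pos_m = ref.sites["pos"].to_numpy() * _MORGANS_PER_BP
    typed_pos = pos_m[typed_ref_idx]
    rho = _switch_probs(typed_pos, n_h_ref, params)

    n_sites = ref.n_sites
    n_typed = typed_ref_idx.size
    n_targets = obs_all.shape[0]
    hds = np.empty((n_targets, n_sites))
    loo = np.empty((n_targets, n_typed))

    # untyped-site interpolation bookkeeping: flanking typed indices + weight
    typed_mask = np.zeros(n_sites, dtype=bool)
    typed_mask[typed_ref_idx] = True
    untyped = np.flatnonzero(~typed_mask)
    right = np.searchsorted(typed_pos, pos_m[untyped])  # first typed at/after
    left = np.clip(right - 1, 0, n_typed - 1)
    right = np.clip(right, 0, n_typed - 1)
    span = typed_pos[right] - typed_pos[left]
    with np.errstate(invalid="ignore", divide="ignore"):
        w_left = np.where(span > 0, (typed_pos[right] - pos_m[untyped]) / np.where(span > 0, span, 1.0), 1.0)
    w_left = np.clip(w_left, 0.0, 1.0)

    for start in range(0, n_targets, _batch):
        sl = slice(start, min(start + _batch, n_targets))
        gamma, gamma_loo = _fb_batch(obs_all[sl], ref_typed, rho, params.err)
        # typed sites: posterior-weighted alleles (emission-dominated)
        hds[sl.start : sl.stop][:, typed_ref_idx] = np.einsum(
            "nth,ht->nt", gamma, ref_typed.astype(np.float64)
        )
        loo[sl] = np.einsum("nth,ht->nt", gamma_loo, ref_typed.astype(np.float64))
        if untyped.size:
            dose_l = np.einsum(
                "nuh,hu->nu", gamma[:, left, :], ref_all[:, untyped]
            )
            dose_r = np.einsum(
                "nuh,hu->nu", gamma[:, right, :], ref_all[:, untyped]
            )
            hds[sl.start : sl.stop][:, untyped] = w_left * dose_l + (1.0 - w_left) * dose_r

    hds = np.clip(hds, 0.0, 1.0)
    loo = np.clip(loo, 0.0, 1.0)

    sites = ref.sites[["contig", "pos", "ref", "alt"]].copy()
    sites["typed"] = typed_mask
    sites["af"] = ref.sites["af"].to_numpy()
    dosage_set = DosageSet(
        sites=sites,
        hds=hds,
        loo=loo,
        typed_idx=typed_ref_idx,
        est_r2=_est_r2_columns(hds),
        sample_ids=list(targets.sample_ids),
        panel_id=panel_id,
    )
    return dosage_set, ImputeLog(typed_sites_absent_from_ref=dropped)
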