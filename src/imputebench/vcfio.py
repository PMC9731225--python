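"""VCF / BED / TSV readers and writers.

File coordinates are 1-based (VCF, manifest TSV) or 0-based half-open
(BED); everything in memory is 0-based.  Haplotype and genotype panels
round-trip through plain-text VCF 4.2 with phased ``|`` or unphased ``/``
GT separators; dosage sets use FORMAT GT/DS/HDS plus INFO AF/R2/TYPED,
with leave-one-out dosages in a sidecar "empirical dose" VCF carrying HDS
at typed sites.  Multi-allelic records are skipped with a count.  Dosages
are serialized at 3 decimals.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .arraymask import GenotypePanel
from .lsimpute import DosageSet
from .synthpop import MISSING, ArrayManifest, HaplotypePanel

__all__ = [
    "write_haplotype_vcf",
    "read_haplotype_vcf",
    "write_genotype_vcf",
    "read_genotype_vcf",
    "write_dosage_vcf",
    "read_dosage_vcf",
    "read_bed",
    "read_site_list",
    "write_manifest_tsv",
    "read_manifest_tsv",
    "config_hash",
]


def config_hash(config: dict) -> str:
    """Short stable hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _provenance_lines(provenance: dict | None) -> list[str]:
    if not provenance:
        return []
    return [f"##imputebench_{k}={v}" for k, v in sorted(provenance.items())]


def _vcf_header(
    contigs: list[str],
    samples: list[str],
    info: list[str],
    formats: list[str],
    provenance: dict | None,
) -> str:
    lines = ["##fileformat=VCFv4.2"]
    lines += _provenance_lines(provenance)
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines += info + formats
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    return "\n".join(lines) + "\n"


_AF_INFO = '##INFO=<ID=AF,Number=A,Type=Float,Description="Non-reference allele frequency">'
_GT_FMT = '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'


def write_haplotype_vcf(
    panel: HaplotypePanel, path: str | Path, provenance: dict | None = None
) -> None:
    """Write a phased panel as VCF with ``|``-separated GT and INFO/AF."""
    path = Path(path)
    contigs = list(dict.fromkeys(panel.sites["contig"]))
    sep = "|" if panel.phased else "/"
    with open(path, "w") as fh:
        fh.write(_vcf_header(contigs, panel.sample_ids, [_AF_INFO], [_GT_FMT], provenance))
        h = panel.haplotypes
        af = panel.sites["af"].to_numpy()
        for j, row in enumerate(panel.sites.itertuples(index=False)):
            a = h[0::2, j]
            b = h[1::2, j]
            gts = "\t".join(
                f"{'.' if x == MISSING else x}{sep}{'.' if y == MISSING else y}"
                for x, y in zip(a, b)
            )
            fh.write(
                f"{row.contig}\t{row.pos + 1}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t"
                f"AF={af[j]:.6g}\tGT\t{gts}\n"
            )


def read_haplotype_vcf(path: str | Path) -> tuple[HaplotypePanel, int]:
    """Read a phased VCF into a panel; returns (panel, n_skipped_records).

    Multi-allelic records are skipped and counted.  Half-calls and missing
    genotypes become ``MISSING`` alleles.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, haps = [], []
    skipped = 0
    phased = True
    for v in vcf:
        if len(v.ALT) != 1:
            skipped += 1
            continue
        g = np.array(v.genotypes)  # (n, 3): allele_a, allele_b, phased
        alleles = g[:, :2].astype(np.int8)
        alleles[alleles < 0] = MISSING
        if not bool(g[:, 2].all()):
            phased = False
        col = np.empty(2 * len(samples), dtype=np.int8)
        col[0::2] = alleles[:, 0]
        col[1::2] = alleles[:, 1]
        rows.append((v.CHROM, v.POS - 1, v.REF, v.ALT[0]))
        haps.append(col)
    if not rows:
        raise ValueError(f"{path}: no usable biallelic records")
    sites = pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt"])
    panel = HaplotypePanel(
        sites=sites,
        haplotypes=np.stack(haps, axis=1),
        sample_ids=samples,
        phased=phased,
    )
    return panel, skipped


def write_genotype_vcf(
    panel: GenotypePanel, path: str | Path, provenance: dict | None = None
) -> None:
    """Write an unphased genotype panel (``/``-separated GT)."""
    path = Path(path)
    contigs = list(dict.fromkeys(panel.sites["contig"]))
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write(_vcf_header(contigs, panel.sample_ids, [], [_GT_FMT], provenance))
        for j, row in enumerate(panel.sites.itertuples(index=False)):
            gts = "\t".join(gt_map[int(x)] for x in panel.genotypes[:, j])
            fh.write(
                f"{row.contig}\t{row.pos + 1}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_genotype_vcf(path: str | Path) -> tuple[GenotypePanel, int]:
    """Read an unphased VCF into a :class:`GenotypePanel`; counts skips."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, genos = [], []
    skipped = 0
    for v in vcf:
        if len(v.ALT) != 1:
            skipped += 1
            continue
        g = np.array(v.genotypes)[:, :2].astype(np.int8)
        col = g.sum(axis=1).astype(np.int8)
        col[(g < 0).any(axis=1)] = MISSING
        rows.append((v.CHROM, v.POS - 1, v.REF, v.ALT[0]))
        genos.append(col)
    if not rows:
        raise ValueError(f"{path}: no usable biallelic records")
    sites = pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt"])
    return (
        GenotypePanel(
            sites=sites, genotypes=np.stack(genos, axis=1), sample_ids=samples
        ),
        skipped,
    )


_DOSE_INFO = [
    _AF_INFO,
    '##INFO=<ID=R2,Number=1,Type=Float,Description="Estimated imputation r2">',
    '##INFO=<ID=TYPED,Number=0,Type=Flag,Description="Site observed on the array">',
]
_DOSE_FMT = [
    _GT_FMT,
    '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Diploid alt dosage">',
    '##FORMAT=<ID=HDS,Number=2,Type=Float,Description="Per-haplotype alt dosages">',
]


def write_dosage_vcf(
    dosages: DosageSet,
    path: str | Path,
    empirical_path: str | Path | None = None,
    provenance: dict | None = None,
) -> None:
    """Write a dosage VCF (GT/DS/HDS; INFO AF/R2/TYPED) at 3 decimals.

    If ``empirical_path`` is given, a sidecar VCF with leave-one-out HDS at
    the typed sites (the meta-imputation input) is written as well.
    """
    path = Path(path)
    contigs = list(dict.fromkeys(dosages.sites["contig"]))
    typed = dosages.typed
    with open(path, "w") as fh:
        fh.write(
            _vcf_header(contigs, dosages.sample_ids, _DOSE_INFO, _DOSE_FMT, provenance)
        )
        hds = dosages.hds
        for j, row in enumerate(dosages.sites.itertuples(index=False)):
            a, b = hds[0::2, j], hds[1::2, j]
            cells = "\t".join(
                f"{round(x)}|{round(y)}:{x + y:.3f}:{x:.3f},{y:.3f}"
                for x, y in zip(a, b)
            )
            af = row.af if not np.isnan(row.af) else 0.0
            info = f"AF={af:.6g};R2={dosages.est_r2[j]:.3f}" + (
                ";TYPED" if typed[j] else ""
            )
            fh.write(
                f"{row.contig}\t{row.pos + 1}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t"
                f"{info}\tGT:DS:HDS\t{cells}\n"
            )
    if empirical_path is not None:
        with open(empirical_path, "w") as fh:
            fh.write(
                _vcf_header(
                    contigs,
                    dosages.sample_ids,
                    _DOSE_INFO[:1],
                    [_DOSE_FMT[0], _DOSE_FMT[2]],
                    provenance,
                )
            )
            for t, j in enumerate(dosages.typed_idx):
                row = dosages.sites.iloc[j]
                a, b = dosages.loo[0::2, t], dosages.loo[1::2, t]
                cells = "\t".join(
                    f"{round(x)}|{round(y)}:{x:.3f},{y:.3f}" for x, y in zip(a, b)
                )
                fh.write(
                    f"{row.contig}\t{row.pos + 1}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t"
                    f"AF={row.af:.6g}\tGT:HDS\t{cells}\n"
                )


def read_dosage_vcf(
    path: str | Path,
    empirical_path: str | Path | None = None,
    panel_id: str = "",
) -> DosageSet:
    """Read a dosage VCF (and optional empirical sidecar) into a DosageSet."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, hds_cols, r2s, typed_flags = [], [], [], []
    for v in vcf:
        if len(v.ALT) != 1:
            continue
        hds = np.asarray(v.format("HDS"), dtype=np.float64)  # (n, 2)
        col = np.empty(2 * len(samples))
        col[0::2] = hds[:, 0]
        col[1::2] = hds[:, 1]
        hds_cols.append(col)
        rows.append(
            (v.CHROM, v.POS - 1, v.REF, v.ALT[0], float(v.INFO.get("AF", 0.0)))
        )
        r2s.append(float(v.INFO.get("R2", 0.0)))
        typed_flags.append(v.INFO.get("TYPED") is not None)
    sites = pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt", "af"])
    sites["typed"] = typed_flags
    sites = sites[["contig", "pos", "ref", "alt", "typed", "af"]]
    typed_idx = np.flatnonzero(typed_flags)
    hds = np.stack(hds_cols, axis=1)

    if empirical_path is not None:
        evcf = VCF(str(empirical_path))
        loo_cols = []
        keys = []
        for v in evcf:
            e = np.asarray(v.format("HDS"), dtype=np.float64)
            col = np.empty(2 * len(samples))
            col[0::2] = e[:, 0]
            col[1::2] = e[:, 1]
            loo_cols.append(col)
            keys.append((v.CHROM, v.POS - 1, v.REF, v.ALT[0]))
        site_keys = pd.Index(
            zip(sites["contig"], sites["pos"], sites["ref"], sites["alt"])
        )
        order = site_keys.get_indexer(pd.Index(keys))
        if (order < 0).any():
            raise ValueError("empirical sidecar contains sites absent from the dosage VCF")
        loo = np.stack(loo_cols, axis=1)[:, np.argsort(order)]
        typed_idx = np.sort(order)
    else:
        loo = hds[:, typed_idx]

    return DosageSet(
        sites=sites,
        hds=hds,
        loo=loo,
        typed_idx=typed_idx,
        est_r2=np.array(r2s),
        sample_ids=samples,
        panel_id=panel_id,
    )


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a 0-based half-open BED into (contig, start, end) rows."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed BED line {i}: {line!r}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}: malformed BED line {i}: {line!r}") from exc
            rows.append({"contig": parts[0], "start": start, "end": end})
    return pd.DataFrame(rows, columns=["contig", "start", "end"])


def read_site_list(path: str | Path) -> set[tuple]:
    """Read an external site list (TSV contig/pos/ref/alt, 1-based, or VCF).

    Returns a set of (contig, 0-based pos, ref, alt) keys.
    """
    path = Path(path)
    if path.suffix == ".vcf" or str(path).endswith(".vcf.gz"):
        keys = set()
        for v in VCF(str(path)):
            for alt in v.ALT:
                keys.add((v.CHROM, v.POS - 1, v.REF, alt))
        return keys
    keys = set()
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("contig"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}: malformed site-list line {i}: {line!r}")
            try:
                pos = int(parts[1]) - 1
            except ValueError as exc:
                raise ValueError(f"{path}: malformed site-list line {i}: {line!r}") from exc
            keys.add((parts[0], pos, parts[2], parts[3]))
    return keys


def write_manifest_tsv(manifest: ArrayManifest, path: str | Path) -> None:
    """Write an array manifest (1-based positions)."""
    df = manifest.sites.copy()
    df["pos"] = df["pos"] + 1
    df["design_pop"] = manifest.design_pop
    df.to_csv(path, sep="\t", index=False)


def read_manifest_tsv(path: str | Path) -> ArrayManifest:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    required = {"contig", "pos", "ref", "alt", "design_pop"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: manifest must have columns {sorted(required)}")
    design = df["design_pop"].iloc[0] if len(df) else ""
    sites = df[["contig", "pos", "ref", "alt"]].copy()
    sites["pos"] = sites["pos"] - 1
    return ArrayManifest(design_pop=design, sites=sites, target_density=len(sites))
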