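"""End-to-end benchmark driver.

Chains the stages simulate -> reference-panel QC -> array design -> array
masking -> imputation (one run per reference panel) -> meta-imputation ->
evaluation -> varLD over a configurable panel x array combination matrix,
writing every artifact with a provenance header (seed + config hash) so a
rerun with the same configuration reproduces identical reports.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .arraymask import mask_to_array
from .evalmetrics import AFBinSpec, EvalReport, evaluate
from .lsimpute import LSParams, impute
from .metaimpute import MetaParams, meta_combine
from .panelqc import QCThresholds, apply_qc_cascade
from .synthpop import (
    HaplotypePanel,
    SimConfig,
    design_array,
    inject_switch_errors,
    simulate_populations,
    split_reference_target,
)
from .varld import VarLDConfig, varld_scan
from . import vcfio

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of one full benchmark run.

    ``seed`` overrides the simulation seed and is propagated to every
    stage; ``n_target`` samples per population are held out as the
    truth-bearing target cohort, the rest form that population's reference
    panel.  Arrays are designed on the QC'd reference panel of each
    population in ``design_pops``.
    """

    sim: SimConfig
    n_target: int
    array_density: int
    seed: int = 0
    out_dir: str = "imputebench_run"
    array_maf_floor: float = 0.05
    array_ld_r2_tag: float = 0.8
    design_pops: list[str] | None = None
    target_pops: list[str] | None = None
    switch_error_rate: float = 0.0
    geno_maf_floor: float = 0.01
    qc: QCThresholds = field(default_factory=QCThresholds)
    mask_bed: str | None = None
    external_site_lists: list[str] = field(default_factory=list)
    ls: LSParams = field(default_factory=LSParams)
    meta: MetaParams = field(default_factory=MetaParams)
    bins: AFBinSpec = field(default_factory=AFBinSpec)
    varld: VarLDConfig = field(default_factory=VarLDConfig)
    run_meta: bool = True
    run_varld: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["sim"] = SimConfig.from_dict(d["sim"])
        for key, sub in [
            ("qc", QCThresholds),
            ("ls", LSParams),
            ("meta", MetaParams),
            ("varld", VarLDConfig),
        ]:
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        if "bins" in d and isinstance(d["bins"], dict):
            d["bins"] = AFBinSpec(
                edges=tuple(d["bins"]["edges"]), af_source=d["bins"].get("af_source", "truth")
            )
        return cls(**d)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Run the full combination matrix and return the artifact manifest.

    The manifest maps artifact roles to file paths and embeds the combined
    evaluation report; it is also written to ``<out_dir>/manifest.json``.
    Rerunning with the same configuration and seed writes byte-identical
    reports.
    """
    out = Path(config.out_dir)
    hashable = {k: v for k, v in config.to_dict().items() if k != "out_dir"}
    chash = vcfio.config_hash(hashable)
    prov = {"seed": config.seed, "config": chash}

    # fail before any compute if referenced inputs are missing
    for p in ([config.mask_bed] if config.mask_bed else []) + list(
        config.external_site_lists
    ):
        if not Path(p).exists():
            raise PipelineError(f"stage 'validate' failed: missing input file {p}")

    for sub in ["sim", "arrays", "qc", "geno", "dosages", "eval", "varld"]:
        (out / sub).mkdir(parents=True, exist_ok=True)

    sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
    panels = _stage("simulate")(simulate_populations)(sim_cfg)
    manifest: dict = {"provenance": prov, "artifacts": {}, "combinations": []}
    art = manifest["artifacts"]

    pop_names = [p.name for p in sim_cfg.pops]
    design_pops = config.design_pops or pop_names
    target_pops = config.target_pops or pop_names

    refs: dict[str, HaplotypePanel] = {}
    truths: dict[str, HaplotypePanel] = {}
    for i, name in enumerate(pop_names):
        ref, tgt = _stage("split")(split_reference_target)(
            panels[name], config.n_target, seed=config.seed + 1000 + i
        )
        refs[name] = ref
        truths[name] = tgt
        path = out / "sim" / f"{name}.vcf"
        _stage("simulate")(vcfio.write_haplotype_vcf)(panels[name], path, prov)
        art[f"sim/{name}"] = str(path)

    mask_df = vcfio.read_bed(config.mask_bed) if config.mask_bed else None
    ext_lists = [vcfio.read_site_list(p) for p in config.external_site_lists]
    qc_refs: dict[str, HaplotypePanel] = {}
    for name in pop_names:
        qc_panel, report = _stage("qc")(apply_qc_cascade)(
            refs[name], mask_df, ext_lists, config.qc
        )
        qc_refs[name] = qc_panel
        vpath = out / "qc" / f"{name}.ref.vcf"
        rpath = out / "qc" / f"{name}.report.json"
        _stage("qc")(vcfio.write_haplotype_vcf)(qc_panel, vpath, prov)
        _write_json(rpath, {"provenance": prov, **report.to_dict()})
        art[f"qc/{name}"] = str(vpath)
        art[f"qc_report/{name}"] = str(rpath)

    arrays = {}
    for name in design_pops:
        arr = _stage("design-array")(design_array)(
            qc_refs[name],
            config.array_density,
            maf_floor=config.array_maf_floor,
            ld_r2_tag=config.array_ld_r2_tag,
            design_pop=name,
        )
        arrays[name] = arr
        path = out / "arrays" / f"{name}.tsv"
        vcfio.write_manifest_tsv(arr, path)
        art[f"array/{name}"] = str(path)

    eval_reports: dict[str, EvalReport] = {}
    for tname in target_pops:
        truth = truths[tname]
        for aname, arr in arrays.items():
            combo_base = f"{tname}_on_{aname}array"
            geno, _ = _stage("mask")(mask_to_array)(
                truth, arr, maf_floor=config.geno_maf_floor
            )
            gpath = out / "geno" / f"{combo_base}.vcf"
            _stage("mask")(vcfio.write_genotype_vcf)(geno, gpath, prov)
            art[f"geno/{combo_base}"] = str(gpath)

            typed_cols = truth.site_keys().get_indexer(geno.site_keys())
            typed_targets = truth.subset_sites(typed_cols)
            if config.switch_error_rate > 0:
                typed_targets = inject_switch_errors(
                    typed_targets, config.switch_error_rate, seed=config.seed + 77
                )

            dosage_sets = []
            for rname in pop_names:
                dos, _ = _stage("impute")(impute)(
                    typed_targets, qc_refs[rname], config.ls, panel_id=rname
                )
                dosage_sets.append(dos)
                dpath = out / "dosages" / f"{combo_base}_ref{rname}.vcf"
                epath = out / "dosages" / f"{combo_base}_ref{rname}.empirical.vcf"
                _stage("impute")(vcfio.write_dosage_vcf)(dos, dpath, epath, prov)
                art[f"dosage/{combo_base}/{rname}"] = str(dpath)
                art[f"empirical/{combo_base}/{rname}"] = str(epath)

                key = f"{combo_base}_ref{rname}"
                eval_reports[key] = _stage("evaluate")(evaluate)(
                    dos, truth, config.bins
                )
                manifest["combinations"].append(
                    {"target": tname, "array": aname, "ref": rname, "mode": "single"}
                )

            if config.run_meta and len(dosage_sets) >= 2:
                meta_dos = _stage("meta")(meta_combine)(
                    dosage_sets, typed_targets, config.meta
                )
                mpath = out / "dosages" / f"{combo_base}_meta.vcf"
                _stage("meta")(vcfio.write_dosage_vcf)(meta_dos, mpath, None, prov)
                art[f"dosage/{combo_base}/meta"] = str(mpath)
                eval_reports[f"{combo_base}_meta"] = _stage("evaluate")(evaluate)(
                    meta_dos, truth, config.bins
                )
                manifest["combinations"].append(
                    {"target": tname, "array": aname, "ref": "+".join(pop_names), "mode": "meta"}
                )

    if config.run_varld and len(pop_names) >= 2:
        a, b = pop_names[0], pop_names[1]
        windows, regions = _stage("varld")(varld_scan)(
            qc_refs[a], qc_refs[b], config.varld
        )
        wpath = out / "varld" / f"{a}_vs_{b}.windows.tsv"
        rpath = out / "varld" / f"{a}_vs_{b}.regions.bed"
        pd.DataFrame(
            [dataclasses.asdict(w) for w in windows]
        ).to_csv(wpath, sep="\t", index=False, float_format="%.6f")
        with open(rpath, "w") as fh:
            for row in regions.itertuples(index=False):
                fh.write(f"{row.contig}\t{row.start}\t{row.end}\t{row.max_standardized:.6f}\n")
        art[f"varld/{a}_vs_{b}"] = str(wpath)
        art[f"varld_regions/{a}_vs_{b}"] = str(rpath)

    report_path = out / "eval" / "report.json"
    _write_json(
        report_path,
        {
            "provenance": prov,
            "reports": {k: v.to_dict() for k, v in sorted(eval_reports.items())},
        },
    )
    art["eval_report"] = str(report_path)

    manifest_path = out / "manifest.json"
    _write_json(manifest_path, manifest)
    return manifest


def _write_json(path: Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
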