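"""End-to-end orchestration: simulate/read -> QC -> relationships -> REML ->
SNP effects -> windows -> gene mapping -> enrichment -> comparison.

Every stage writes its TSV outputs under the run directory and the manifest
records the configuration, seed, input checksums and output paths, so a run
is self-describing and two runs with the same seed are byte-identical in
their tabular outputs (the manifest's wall timestamps excepted).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .compare import compare, summarize
from .effects import compute_snp_effects
from .enrichment import enrich, enrichment_frame
from .genes import assign_nearest_gene, tabulate_bins
from .model import RepeatabilityModel
from .relationships import build_relationships
from .simulate import (SimulationSpec, simulate_annotation, simulate_dataset,
                       simulate_pathways)
from .windows import aggregate, build_windows, select_snps


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    input_checksums: dict
    outputs: dict
    timestamps: dict

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_simulation_inputs(spec: SimulationSpec, out_dir: str | Path,
                            with_annotation: bool = True) -> dict:
    """Emit the analysis input files for a simulated dataset (plus truth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = simulate_dataset(spec)
    paths = {
        "pedigree": out / "pedigree.tsv",
        "phenotypes": out / "phenotypes.tsv",
        "genotypes": out / "genotypes.tsv",
        "marker_map": out / "marker_map.tsv",
        "truth": out / "truth.tsv",
    }
    sio.write_pedigree(data.pedigree, paths["pedigree"])
    sio.write_phenotypes(data.phenotypes, paths["phenotypes"])
    sio.write_genotypes(data.genotypes, paths["genotypes"], paths["marker_map"])
    sio.write_table(data.truth.to_frame(), paths["truth"])
    if with_annotation:
        ann = simulate_annotation(data.genotypes)
        causal = []
        if len(data.truth.qtl):
            hits = assign_nearest_gene(
                data.genotypes.marker_map.merge(data.truth.qtl[["marker"]], on="marker"),
                ann)
            causal = [g for g in hits["gene_id"] if g != "NA"]
        db = simulate_pathways(ann, causal_genes=causal,
                               rng=np.random.default_rng(spec.seed + 7))
        paths["annotation"] = out / "annotation.bed"
        paths["pathways"] = out / "pathways.gmt"
        sio.write_annotation_bed(ann, paths["annotation"])
        sio.write_gmt(db, paths["pathways"])
    return {k: str(v) for k, v in paths.items()}


def run_all(config: sio.RunConfig, out_dir: str | Path,
            sim_spec: SimulationSpec | None = None,
            inputs: dict | None = None) -> RunManifest:
    """Execute the full pipeline into ``out_dir``.

    Either ``sim_spec`` (synthetic run; the config seed overrides the spec
    seed) or ``inputs`` (paths: pedigree, phenotypes, genotypes, marker_map,
    annotation, pathways) must be given.  All stage outputs are TSV.
    """
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timestamps = {"start": t0}
    outputs: dict[str, str] = {}

    if sim_spec is None and inputs is None:
        raise sio.DataError("run_all needs a SimulationSpec or input paths")
    if sim_spec is not None:
        sim_spec = replace(sim_spec, seed=config.seed)
        inputs = write_simulation_inputs(sim_spec, out / "inputs")
    else:
        needed = ["pedigree", "phenotypes", "genotypes", "marker_map",
                  "annotation", "pathways"]
        missing = [k for k in needed if k not in inputs or not Path(inputs[k]).exists()]
        if missing:
            raise sio.DataError(f"missing input file(s) before any compute: {missing}")

    ped = sio.read_pedigree(inputs["pedigree"])
    phen = sio.read_phenotypes(inputs["phenotypes"])
    geno = sio.read_genotypes(inputs["genotypes"], inputs["marker_map"])
    ann = sio.read_annotation(inputs["annotation"])
    db = sio.read_gmt(inputs["pathways"])
    checksums = {k: _sha256(Path(v)) for k, v in inputs.items()}

    # QC
    geno_qc, qc_report = sio.qc_filter(geno, config.min_call_rate, config.min_maf)
    outputs["qc_report"] = str(out / "qc_report.tsv")
    sio.write_table(qc_report, outputs["qc_report"])

    # relationships + REML
    rel = build_relationships(ped, geno_qc)
    model = RepeatabilityModel(phen, relationships=rel)
    res = model.fit(max_iter=config.reml_max_iter, tol=config.reml_tol)
    outputs["variance_components"] = str(out / "variance_components.tsv")
    sio.write_table(res.vc.to_frame(), outputs["variance_components"])
    gebv = res.gebv.reset_index()
    gebv["genotyped"] = gebv["animal"].isin(set(rel.genotyped_ids))
    outputs["gebv"] = str(out / "gebv.tsv")
    sio.write_table(gebv, outputs["gebv"])
    conv = pd.DataFrame({"iteration": np.arange(len(res.loglik_path)),
                         "restricted_loglik": res.loglik_path})
    outputs["convergence"] = str(out / "convergence.tsv")
    sio.write_table(conv, outputs["convergence"])

    # SNP effects
    eff = compute_snp_effects(res.gebv_for(rel.genotyped_ids), geno_qc, rel,
                              res.vc.sigma_a2, phen.traits)
    outputs["snp_effects"] = str(out / "snp_effects.tsv")
    sio.write_table(eff.to_frame(), outputs["snp_effects"])

    # windows, selection, gene mapping, enrichment
    background = sorted(ann.gene_ids & db.all_genes)
    scheme_results = {}
    scheme_genes = {}
    assignments = {}
    mm = geno_qc.marker_map
    for mode in config.overlap_modes:
        for w in config.window_sizes:
            scheme = build_windows(mm, w, mode)
            table = aggregate(scheme, eff)
            outputs[f"windows_{scheme.label}"] = str(out / f"windows_{scheme.label}.tsv")
            sio.write_table(table, outputs[f"windows_{scheme.label}"])
            sel = select_snps(table, scheme, config.thresholds[w], marker_map=mm)
            union_markers = sorted(set().union(*sel.values())) if sel else []
            sel_df = pd.concat([
                pd.DataFrame({"trait": t, "marker": sorted(ms)})
                for t, ms in sel.items()], ignore_index=True) if sel else \
                pd.DataFrame(columns=["trait", "marker"])
            outputs[f"selected_{scheme.label}"] = str(out / f"selected_{scheme.label}.tsv")
            sio.write_table(sel_df, outputs[f"selected_{scheme.label}"])
            snp_df = mm[mm["marker"].isin(union_markers)]
            asg = assign_nearest_gene(snp_df, ann)
            assignments[scheme.label] = asg
            outputs[f"genes_{scheme.label}"] = str(out / f"genes_{scheme.label}.tsv")
            sio.write_table(asg, outputs[f"genes_{scheme.label}"])
            genes = set(asg.loc[asg["gene_id"] != "NA", "gene_id"])
            scheme_genes[scheme.label] = genes
            er = enrich(genes, db, background, alpha=config.significance_alpha)
            scheme_results[scheme.label] = er
            outputs[f"enrichment_{scheme.label}"] = str(out / f"enrichment_{scheme.label}.tsv")
            sio.write_table(enrichment_frame(er, scheme.label),
                            outputs[f"enrichment_{scheme.label}"])

    bins = tabulate_bins(assignments)
    outputs["bin_counts"] = str(out / "bin_counts.tsv")
    sio.write_table(bins, outputs["bin_counts"])

    cm = compare(scheme_results, scheme_genes, db)
    outputs["np_matrix"] = str(out / "np_matrix.tsv")
    outputs["ng_matrix"] = str(out / "ng_matrix.tsv")
    cm.frame("NP").to_csv(outputs["np_matrix"], sep="\t")
    cm.frame("NG").to_csv(outputs["ng_matrix"], sep="\t")
    outputs["comparison_summary"] = str(out / "comparison_summary.txt")
    Path(outputs["comparison_summary"]).write_text(summarize(cm) + "\n")

    timestamps["end"] = time.time()
    from . import __version__
    manifest = RunManifest(
        config=dataclasses.asdict(config), seed=config.seed, version=__version__,
        input_checksums=checksums, outputs=outputs, timestamps=timestamps)
    manifest.to_json(out / "manifest.json")
    return manifest
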