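"""End-to-end orchestration with a config file and a reproducible manifest.

The pipeline reads a reference FASTA + GFF3 gene table, per-sample SAM
alignments, and a sample metadata table, then writes per-sample SNV and
diversity tables, linkage summaries, pairwise FST / PCoA / divergence
results, pangenome differential-presence tables, and temporal correlation
tables, plus a machine-readable run manifest.  All thresholds default to
the study values; every override is recorded with its provenance in the
manifest and the run log.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import GenomeAnnotation, read_annotation
from .divergence import (consensus_divergence_time, fst_outlier_test,
                         gene_fst_table, pairwise_mean_fst, pcoa_cailliez)
from .linkage import (enumerate_linked_pairs, linkage_decay_curve,
                      mean_genome_r2, pairs_to_frame)
from .pangenome import (basin_specific_genes, differential_gene_presence,
                        gene_coverage_matrix)
from .profiling import (build_pileup, call_snvs, diversity_profile,
                        population_detection)
from .reads import ReadPairSet
from .temporal import covariate_correlated_snvs, snv_frequency_matrix

logger = logging.getLogger("micropopgen")

#: study-default thresholds, the provenance baseline for the manifest
DEFAULT_THRESHOLDS: dict[str, float] = {
    "min_read_identity": 0.94,
    "min_coverage": 5,
    "min_allele_freq": 0.05,
    "min_allele_count": 2,
    "detection_min_coverage": 5.0,
    "detection_min_breadth": 0.5,
    "linkage_max_dist": 420,
    "linkage_min_pairs": 20,
    "linkage_rarefy_to": 20,
    "linkage_reps": 100,
    "fst_min_depth": 20,
    "fst_sd_filter": 2.0,
    "mask_threshold": 3.0,
    "detect_threshold": 0.10,
    "differential_p": 0.001,
    "basin_gate_p": 0.01,
    "temporal_min_coverage": 20,
    "temporal_min_points": 8,
    "temporal_alpha": 0.05,
    "mu": 1e-10,
    "generation_days": 7.0,
}

FLOAT_FORMAT = "%.6g"


@dataclass
class PipelineConfig:
    reference_fasta: str
    genes_gff3: str
    samples: list[dict]              # id, sam, site, iso_date, temperature_c
    output_dir: str
    seed: int = 0
    thresholds: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            reference_fasta=raw["reference_fasta"],
            genes_gff3=raw["genes_gff3"],
            samples=raw["samples"],
            output_dir=raw["output_dir"],
            seed=int(raw.get("seed", 0)),
            thresholds=dict(raw.get("thresholds", {})),
        )

    def resolved_thresholds(self) -> dict[str, float]:
        unknown = set(self.thresholds) - set(DEFAULT_THRESHOLDS)
        if unknown:
            raise ValueError(f"unknown thresholds: {sorted(unknown)}")
        return {**DEFAULT_THRESHOLDS, **self.thresholds}

    def validate(self) -> None:
        if not self.samples:
            raise ValueError("empty sample list")
        for path in [self.reference_fasta, self.genes_gff3] + \
                [s["sam"] for s in self.samples]:
            if not Path(path).is_file():
                raise FileNotFoundError(f"input not readable: {path}")
        self.resolved_thresholds()


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(frame: pd.DataFrame, path: Path, index: bool = True) -> None:
    frame.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=index)


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on the configured inputs; returns the manifest."""
    config.validate()
    thr = config.resolved_thresholds()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out / "run.log")
    for key, value in thr.items():
        tag = "user-override" if key in config.thresholds else "study-default"
        logger.info("threshold %s = %s [%s]", key, value, tag)

    annotation = read_annotation(config.reference_fasta, config.genes_gff3)
    meta = pd.DataFrame(config.samples).set_index("id")

    pileups = {}
    detection_rows = []
    snv_tables = {}
    for sample in meta.index:
        reads = ReadPairSet.from_sam(str(meta.loc[sample, "sam"]), annotation)
        pileup = build_pileup(reads, annotation, thr["min_read_identity"])
        pileups[sample] = pileup
        detected = population_detection(
            pileup, thr["detection_min_coverage"], thr["detection_min_breadth"])
        snvs = call_snvs(pileup, annotation, int(thr["min_coverage"]),
                         thr["min_allele_freq"], int(thr["min_allele_count"]))
        snv_tables[sample] = snvs
        prof = diversity_profile(pileup, annotation, snvs,
                                 int(thr["min_coverage"]))
        detection_rows.append({
            "sample": sample, "mean_coverage": pileup.mean_coverage,
            "breadth": pileup.breadth, "detected": detected,
            "n_snvs": len(snvs), "pi": prof.pi_genome,
            "pnps": prof.pnps_genome, "pi_neutral": prof.pi_neutral,
            "n_neutral_sites": prof.n_neutral_sites,
        })
        _write(snvs, out / f"{sample}.snvs.tsv", index=False)
        gene_table = pd.DataFrame({
            "pi": prof.pi_gene, "pnps": prof.pnps_gene})
        _write(gene_table, out / f"{sample}.diversity.tsv")

        pairs = enumerate_linked_pairs(
            snvs, reads, int(thr["linkage_max_dist"]),
            int(thr["linkage_min_pairs"]),
            rarefy_to=int(thr["linkage_rarefy_to"]),
            n_reps=int(thr["linkage_reps"]), seed=config.seed)
        _write(pairs_to_frame(pairs), out / f"{sample}.linkage_pairs.tsv",
               index=False)
        _write(linkage_decay_curve(pairs, max_dist=int(thr["linkage_max_dist"])),
               out / f"{sample}.linkage_decay.tsv", index=False)
        if pairs:
            logger.info("%s: mean r2 = %.4f over %d pairs", sample,
                        mean_genome_r2(pairs), len(pairs))
    summary = pd.DataFrame(detection_rows).set_index("sample")
    _write(summary, out / "sample_summary.tsv")

    results: dict = {"samples": summary.to_dict(orient="index")}

    # between-sample differentiation
    deep = {s: p for s, p in pileups.items()
            if p.mean_coverage > thr["fst_min_depth"]}
    if len(deep) >= 2:
        fst_matrix = pairwise_mean_fst(
            deep, annotation, thr["fst_min_depth"], thr["fst_min_depth"],
            thr["fst_sd_filter"])
        _write(fst_matrix, out / "pairwise_fst.tsv")
        pcoa = pcoa_cailliez(fst_matrix.clip(lower=0.0))
        _write(pcoa.coordinates, out / "pcoa_coordinates.tsv")
        results["pcoa_explained"] = pcoa.explained.tolist()

        sites = sorted(meta["site"].unique())
        if len(sites) == 2:
            rep = {site: max(
                (s for s in deep if meta.loc[s, "site"] == site),
                key=lambda s: deep[s].mean_coverage, default=None)
                for site in sites}
            if all(rep.values()):
                a, b = rep[sites[0]], rep[sites[1]]
                genes = gene_fst_table(deep[a], deep[b], annotation,
                                       thr["fst_min_depth"],
                                       thr["fst_sd_filter"],
                                       thr["fst_min_depth"])
                _write(genes, out / "gene_fst.tsv", index=False)
                if genes["fst"].notna().sum() >= 10:
                    outliers = fst_outlier_test(
                        genes.set_index("gene_id")["fst"])
                    _write(outliers, out / "fst_outliers.tsv")
                    results["n_fst_outliers"] = int(outliers["outlier"].sum())
                div = consensus_divergence_time(
                    deep[a], deep[b], annotation, thr["mu"],
                    thr["generation_days"])
                results["divergence"] = div.__dict__
                (out / "divergence.json").write_text(
                    json.dumps(div.__dict__, indent=2))

    # pangenome flexibility from relative gene coverage
    if meta["site"].nunique() == 2 and \
            meta.groupby("site").size().min() >= 2:
        matrix = gene_coverage_matrix(
            pileups, annotation, meta["site"].to_dict(),
            thr["mask_threshold"])
        diff = differential_gene_presence(matrix, thr["differential_p"])
        classes = basin_specific_genes(matrix, diff, thr["detect_threshold"],
                                       thr["basin_gate_p"])
        diff["classification"] = classes.reindex(diff.index)
        _write(diff, out / "differential_genes.tsv")
        results["n_differential_genes"] = int(diff["differential"].sum())
        results["n_basin_specific"] = int(
            (classes != "shared").sum()) if len(classes) else 0

    # temporal trajectories per site
    for site, grp in meta.groupby("site"):
        if len(grp) < 4 or "temperature_c" not in grp:
            continue
        covariate = grp["temperature_c"].astype(float)
        traj = snv_frequency_matrix(
            {s: pileups[s] for s in grp.index}, annotation, covariate,
            int(thr["temporal_min_coverage"]))
        _write(traj.frequencies, out / f"{site}.trajectories.tsv")
        corr = covariate_correlated_snvs(
            traj, int(thr["temporal_min_points"]), thr["temporal_alpha"])
        _write(corr, out / f"{site}.temperature_correlation.tsv")
        results[f"n_correlated_snvs_{site}"] = int(corr["correlated"].sum())

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            k: {"value": v,
                "provenance": ("user-override" if k in config.thresholds
                               else "study-default")}
            for k, v in thr.items()},
        "inputs": {
            "reference_fasta": _sha256(config.reference_fasta),
            "genes_gff3": _sha256(config.genes_gff3),
            **{s["id"]: _sha256(s["sam"]) for s in config.samples},
        },
        "results": results,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=_jsonify))
    return manifest


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _setup_logging(logfile: Path) -> None:
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    fmt = logging.Formatter(
        "%(asctime)s %(levelname)s %(message)s", "%Y-%m-%dT%H:%M:%S")
    for handler in (logging.StreamHandler(sys.stderr),
                    logging.FileHandler(logfile, mode="w")):
        handler.setFormatter(fmt)
        logger.addHandler(handler)
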