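"""End-to-end orchestration: merge -> filter -> sets -> summaries ->
annotation -> windows/outliers -> enrichment, from one YAML config.

Every stage is a pure function of (inputs, config); the run manifest records
package/library versions, the full effective config, per-stage counts and
output checksums, so a run is reproducible from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import annotate_matrix, tabulate_annotation
from .enrich import enrich, read_term_map
from .filters import FilterConfig, apply_filters
from .genemodels import read_gene_models
from .io import (
    ReferenceGenome,
    read_bed_mask,
    read_site_list,
    read_vcf,
    write_merged_vcf,
)
from .sets import sharing_table, shared_within_species, specific_snvs
from .summaries import sample_summary, spectra, summary_table
from .variants import merge_samples
from .windows import bin_counts, cooks_outliers, outlier_genes

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for context."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    samples: dict[str, str]  # name -> VCF path, roster order
    reference_fasta: str
    gff3: str | None = None
    mask_bed: str | None = None
    outgroup_sites: str | None = None
    pairs: list[list[str]] = field(default_factory=list)  # conspecific pairs
    drop_missing: bool = True
    drop_triallelic: bool = True
    drop_cpg: bool = True
    proximity_bp: int = 5
    outgroup_mode: str = "any"
    flank_bp: int = 1000
    splice_bp: int = 2
    window_size: int = 50_000
    multiplier: float = 30.0
    gene_term_tsv: str | None = None
    term_names_tsv: str | None = None
    enrich_min_k: int = 3
    enrich_size_range: tuple[int, int] = (5, 500)
    denom_bp: int | None = None
    outdir: str = "macdiv_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "enrich_size_range" in raw:
            raw["enrich_size_range"] = tuple(raw["enrich_size_range"])
        return cls(**raw)

    def validate(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample names in roster")
        missing = [p for p in self._paths() if p and not Path(p).exists()]
        if missing:
            raise ValueError(f"missing input paths: {missing}")
        for pair in self.pairs:
            if len(pair) != 2 or any(s not in self.samples for s in pair):
                raise ValueError(f"bad conspecific pair {pair}")
        if self.gff3 is None and self.gene_term_tsv is not None:
            raise ValueError("enrichment requires gene models (gff3)")

    def _paths(self) -> list[str | None]:
        return [*self.samples.values(), self.reference_fasta, self.gff3,
                self.mask_bed, self.outgroup_sites, self.gene_term_tsv,
                self.term_names_tsv]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest dict."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict = {}
    outputs: dict[str, Path] = {}
    t0 = time.perf_counter()

    def stage(name):
        logger.info("stage %s (t=%.1fs)", name, time.perf_counter() - t0)

    try:
        stage("merge")
        genome = ReferenceGenome.from_fasta(cfg.reference_fasta)
        per_sample = {s: read_vcf(p, s) for s, p in cfg.samples.items()}
        counts["input_records"] = {s: len(v) for s, v in per_sample.items()}
        m = merge_samples(per_sample, roster=list(cfg.samples),
                          reference_lengths=genome.lengths)
        counts["merged_sites"] = m.n_sites
        outputs["merged_vcf"] = outdir / "merged.vcf"
        write_merged_vcf(m, outputs["merged_vcf"])
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("merge", exc) from exc

    try:
        stage("filter")
        mask = read_bed_mask(cfg.mask_bed) if cfg.mask_bed else None
        fcfg = FilterConfig(
            drop_missing=cfg.drop_missing,
            drop_triallelic=cfg.drop_triallelic,
            drop_cpg=cfg.drop_cpg,
            proximity_bp=cfg.proximity_bp,
            mask=mask,
        )
        m, report = apply_filters(m, genome, fcfg)
        counts["filter_removed"] = dict(report.removed)
        counts["filtered_sites"] = m.n_sites
        outputs["filter_report"] = outdir / "filter_report.tsv"
        report.to_tsv(outputs["filter_report"])
        outputs["filtered_vcf"] = outdir / "filtered.vcf"
        write_merged_vcf(m, outputs["filtered_vcf"])
    except Exception as exc:
        raise PipelineError("filter", exc) from exc

    try:
        stage("sets")
        outgroup = (read_site_list(cfg.outgroup_sites)
                    if cfg.outgroup_sites else set())
        sharing = sharing_table(m)
        outputs["sharing"] = outdir / "sharing.tsv"
        sharing.to_csv(outputs["sharing"], sep="\t", index=False)
        counts["sharing_subsets"] = len(sharing)
        paired = {s for pair in cfg.pairs for s in pair}
        units: dict[str, list[str]] = {s: [s] for s in cfg.samples
                                       if s not in paired}
        for a, b in cfg.pairs:
            units[f"{a}+{b}"] = [a, b]
        specific = {
            name: specific_snvs(m, unit, outgroup, cfg.outgroup_mode)
            for name, unit in units.items()
        }
        counts["specific"] = {k: int(len(v)) for k, v in specific.items()}
        outputs["specific_sites"] = outdir / "specific_sites.tsv"
        with open(outputs["specific_sites"], "w") as fh:
            fh.write("unit\tchrom\tpos\n")
            for name, idx in specific.items():
                for i in idx:
                    fh.write(f"{name}\t{m.sites.at[int(i), 'chrom']}\t"
                             f"{m.sites.at[int(i), 'pos']}\n")
    except Exception as exc:
        raise PipelineError("sets", exc) from exc

    try:
        stage("summaries")
        denom = cfg.denom_bp or sum(genome.lengths.values())
        summaries = []
        for s in cfg.samples:
            # per-sample specific set: the sample's own unit if unpaired
            idx = specific.get(s, np.array([], dtype=int))
            summaries.append(sample_summary(m, s, idx, denom))
        for a, b in cfg.pairs:
            shared = shared_within_species(m, a, b)
            idx = specific[f"{a}+{b}"]
            pseudo = sample_summary(shared, f"{a}+{b}", None, denom)
            pseudo.n_specific = int(len(idx))
            pseudo.pct_specific = (round(100 * len(idx) / pseudo.n_snvs, 2)
                                   if pseudo.n_snvs else float("nan"))
            summaries.append(pseudo)
        table2 = summary_table(summaries)
        outputs["summary"] = outdir / "summary.tsv"
        table2.to_csv(outputs["summary"], sep="\t", index=False)
    except Exception as exc:
        raise PipelineError("summaries", exc) from exc

    annotation = None
    if cfg.gff3:
        try:
            stage("annotate")
            genes = read_gene_models(cfg.gff3, genome)
            annotation = annotate_matrix(m, genes, genome,
                                         cfg.flank_bp, cfg.splice_bp)
            outputs["annotation"] = outdir / "annotation.tsv"
            annotation.to_csv(outputs["annotation"], sep="\t", index=False)
            reg, eff = tabulate_annotation(annotation)
            outputs["region_table"] = outdir / "region_table.tsv"
            reg.to_csv(outputs["region_table"], sep="\t", index=False)
            outputs["effect_table"] = outdir / "effect_table.tsv"
            eff.to_csv(outputs["effect_table"], sep="\t", index=False)
            counts["regions"] = annotation["region"].value_counts().to_dict()
            counts["effects"] = (annotation["effect"].dropna()
                                 .value_counts().to_dict())
            sp = spectra(m.sites["ref"], m.sites["alt"], annotation)
            outputs["spectra"] = outdir / "spectra.tsv"
            with open(outputs["spectra"], "w") as fh:
                for label, series in [
                    ("substitution", sp.substitutions),
                    ("codon_change", sp.codon_changes),
                    ("aa_change", sp.aa_changes_unordered),
                ]:
                    for key, n in series.items():
                        fh.write(f"{label}\t{key}\t{n}\n")
        except Exception as exc:
            raise PipelineError("annotate", exc) from exc

    if annotation is not None:
        try:
            stage("windows")
            carriers = m.carrier_matrix()
            is_ns = (annotation["effect"] == "nonsynonymous").to_numpy()
            ns_positions = {}
            for j, s in enumerate(cfg.samples):
                sel = is_ns & carriers[:, j]
                sub = m.sites[sel]
                ns_positions[s] = {
                    c: g["pos"].to_numpy()
                    for c, g in sub.groupby("chrom", sort=False)
                }
            wms = bin_counts(ns_positions, genome.lengths, cfg.window_size)
            outputs["window_counts"] = outdir / "window_counts.tsv"
            with open(outputs["window_counts"], "w") as fh:
                fh.write("chrom\twindow\t" + "\t".join(cfg.samples) + "\n")
                for chrom, wm in wms.items():
                    for k in range(wm.n_windows):
                        row = "\t".join(str(int(x)) for x in wm.counts[k])
                        fh.write(f"{chrom}\t{k}\t{row}\n")
            results = {c: cooks_outliers(wm, cfg.multiplier)
                       for c, wm in wms.items()}
            beds = [r.to_bed() for r in results.values() if r is not None]
            bed = (pd.concat(beds, ignore_index=True) if beds
                   else pd.DataFrame(columns=["chrom", "start", "end",
                                              "window", "max_d"]))
            outputs["outlier_windows"] = outdir / "outlier_windows.bed"
            bed.to_csv(outputs["outlier_windows"], sep="\t", index=False,
                       header=False)
            counts["flagged_windows"] = int(len(bed))
            genes_df = outlier_genes(results, genes, ns_positions)
            outputs["outlier_genes"] = outdir / "outlier_genes.tsv"
            genes_df.to_csv(outputs["outlier_genes"], sep="\t", index=False)
            counts["outlier_genes"] = int(len(genes_df))
        except Exception as exc:
            raise PipelineError("windows", exc) from exc

        if cfg.gene_term_tsv:
            try:
                stage("enrich")
                background = set(genes.gene_spans)
                terms = read_term_map(cfg.gene_term_tsv, background,
                                      cfg.term_names_tsv)
                study = set(genes_df["gene_id"])
                res = enrich(study, terms, cfg.enrich_min_k,
                             cfg.enrich_size_range)
                outputs["enrichment"] = outdir / "enrichment.tsv"
                res.to_csv(outputs["enrichment"], sep="\t", index=False)
                counts["enriched_terms"] = int(res["significant"].sum()) if len(res) else 0
            except Exception as exc:
                raise PipelineError("enrich", exc) from exc

    stage("manifest")
    cfg_dict = asdict(cfg)
    cfg_dict["enrich_size_range"] = list(cfg.enrich_size_range)
    cfg_json = json.dumps(cfg_dict, sort_keys=True)
    manifest = {
        "macdiv_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "counts": counts,
        "outputs": {k: {"path": str(p), "sha256": _sha256(p)}
                    for k, p in outputs.items()},
    }
    manifest["manifest_sha256"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True, default=str).encode()
    ).hexdigest()
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
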