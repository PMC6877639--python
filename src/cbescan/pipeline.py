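"""End-to-end orchestration of the analysis stages from a config file.

A run executes, in order and each optionally skippable: somatic filtering of
allele-count tables, spectrum summaries and fold changes, TCW/context
signature analysis, PAM-proximity scanning with a sampled genomic
background, off-target intersection, and inter-clone comparison.  Every run
emits TSV/JSON artifacts plus a manifest recording parameters, the seed and
SHA-256 checksums of all inputs and outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import comparative, context_signature, genome_scan, somatic_filter, spectrum
from .genome_io import (Genome, VariantCatalog, read_counts_table, read_fasta,
                        read_offtarget_table, read_vcf, write_vcf)

logger = logging.getLogger("cbescan")

ALL_STAGES = ("filter", "spectrum", "signature", "pamscan", "offtarget", "compare")


class ConfigError(ValueError):
    """The analysis config is invalid or references missing files."""


@dataclass
class AnalysisConfig:
    """Validated pipeline configuration (see ``from_file`` for the key layout)."""

    genome_path: Path
    counts_paths: dict[str, Path] = field(default_factory=dict)
    catalog_paths: dict[str, Path] = field(default_factory=dict)
    offtarget_path: Path | None = None
    thresholds: somatic_filter.FilterThresholds = somatic_filter.FilterThresholds()
    window: context_signature.ContextWindow = context_signature.ContextWindow()
    pam: genome_scan.PamWindowSpec = genome_scan.PamWindowSpec()
    background_n_samples: int = 1_000_000
    control_clones: tuple[str, ...] = spectrum.DEFAULT_CONTROL_CLONES
    grouping: dict[str, list[str]] = field(default_factory=dict)
    cg_logo_min_count: int = 40  # C:G>G:C logo only above this class count
    chrom_min_total: int = 500
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES

    @classmethod
    def from_mapping(cls, raw: Mapping[str, Any], base: Path = Path(".")) -> "AnalysisConfig":
        def p(x) -> Path:
            q = Path(x)
            return q if q.is_absolute() else base / q

        genome_path = p(raw["genome"]) if "genome" in raw else None
        if genome_path is None or not genome_path.exists():
            raise ConfigError(f"genome FASTA missing or not found: {genome_path}")
        counts = {k: p(v) for k, v in raw.get("counts", {}).items()}
        catalogs = {k: p(v) for k, v in raw.get("catalogs", {}).items()}
        for name, path in {**counts, **catalogs}.items():
            if not path.exists():
                raise ConfigError(f"input for clone {name!r} not found: {path}")
        offt = p(raw["offtargets"]) if raw.get("offtargets") else None
        if offt is not None and not offt.exists():
            raise ConfigError(f"off-target table not found: {offt}")
        thr = somatic_filter.FilterThresholds(**raw.get("thresholds", {}))
        window = context_signature.ContextWindow(**raw.get("context_window", {}))
        pam = genome_scan.PamWindowSpec(**raw.get("pam", {}))
        stages = tuple(raw.get("stages", ALL_STAGES))
        unknown = set(stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stage(s): {sorted(unknown)}")
        return cls(
            genome_path=genome_path, counts_paths=counts, catalog_paths=catalogs,
            offtarget_path=offt, thresholds=thr, window=window, pam=pam,
            background_n_samples=int(raw.get("background_n_samples", 1_000_000)),
            control_clones=tuple(raw.get("control_clones",
                                         spectrum.DEFAULT_CONTROL_CLONES)),
            grouping={k: list(v) for k, v in raw.get("grouping", {}).items()},
            cg_logo_min_count=int(raw.get("cg_logo_min_count", 40)),
            chrom_min_total=int(raw.get("chrom_min_total", 500)),
            seed=int(raw.get("seed", 0)), stages=stages)

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_mapping(raw, base=path.parent)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: AnalysisConfig, outdir: str | Path) -> dict:
    """Execute the configured stages; return (and write) the run report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = read_fasta(config.genome_path)
    report: dict[str, Any] = {"seed": config.seed, "stages": {}}
    outputs: list[Path] = []

    catalogs: dict[str, VariantCatalog] = {
        cid: read_vcf(path, genome, clone_id=cid)
        for cid, path in config.catalog_paths.items()}

    if "filter" in config.stages and config.counts_paths:
        for cid, path in config.counts_paths.items():
            sites = read_counts_table(path)
            retained, calls = somatic_filter.filter_somatic(
                sites, config.thresholds, clone_id=cid)
            catalogs[cid] = retained
            vcf_out = outdir / f"{cid}.somatic.vcf"
            write_vcf(retained, vcf_out, genome)
            audit_out = outdir / f"{cid}.audit.tsv"
            somatic_filter.calls_to_frame(calls).to_csv(audit_out, sep="\t", index=False)
            outputs += [vcf_out, audit_out]
            logger.info("filter[%s]: %d/%d retained", cid, len(retained), len(sites))
        report["stages"]["filter"] = {
            cid: len(cat) for cid, cat in catalogs.items()
            if cid in config.counts_paths}

    summaries = {cid: spectrum.summarize_catalog(cat) for cid, cat in catalogs.items()}

    if "spectrum" in config.stages and summaries:
        table_out = outdir / "spectrum.tsv"
        spectrum.write_spectrum_table(list(summaries.values()), table_out)
        outputs.append(table_out)
        controls = [summaries[c] for c in config.control_clones if c in summaries]
        fc_report = {}
        if controls:
            import pandas as pd
            rows = []
            for cid, summ in summaries.items():
                if cid in config.control_clones:
                    continue
                for rec in spectrum.fold_changes(summ, controls):
                    rows.append((rec.clone_id, rec.mutation_class, rec.clone_count,
                                 rec.control_mean, rec.fold_change))
            fc_out = outdir / "fold_changes.tsv"
            pd.DataFrame(rows, columns=["clone", "class", "count", "control_mean",
                                        "fold_change"]).to_csv(fc_out, sep="\t",
                                                               index=False)
            outputs.append(fc_out)
            fc_report["n_records"] = len(rows)
        report["stages"]["spectrum"] = {
            "totals": {cid: s.total for cid, s in summaries.items()}, **fc_report}

    if "signature" in config.stages and catalogs:
        sig_report = {}
        for cid, cat in catalogs.items():
            per_class = {}
            for cls in ("C:G>T:A", "C:G>G:C"):
                if cls == "C:G>G:C" and summaries[cid].counts[cls] <= config.cg_logo_min_count:
                    logger.info("signature[%s]: %s count %d <= %d, logo skipped",
                                cid, cls, summaries[cid].counts[cls],
                                config.cg_logo_min_count)
                    continue
                contexts, excluded = context_signature.extract_contexts(
                    genome, cat, config.window, classes=(cls,))
                if not contexts:
                    continue
                matrix = context_signature.build_context_matrix(contexts)
                tag = cls.replace(":", "").replace(">", "_")
                mat_out = outdir / f"{cid}.{tag}.context.tsv"
                matrix.to_frame().to_csv(mat_out, sep="\t", index=False)
                fasta_out = outdir / f"{cid}.{tag}.contexts.fa"
                context_signature.contexts_to_fasta(contexts, fasta_out)
                outputs += [mat_out, fasta_out]
                per_class[cls] = {"n_contexts": matrix.n, "n_excluded": len(excluded),
                                  "tcw_fraction": context_signature.tcw_fraction(contexts)}
            enr = context_signature.tcw_enrichment(cat, genome, config.window)
            per_class["enrichment"] = {
                "observed_fraction": enr.observed_fraction,
                "background_fraction": enr.background_fraction,
                "enrichment_ratio": enr.enrichment_ratio,
                "p_value": enr.p_value, "n": enr.n_contexts,
                "n_excluded": enr.n_excluded}
            sig_report[cid] = per_class
        sig_out = outdir / "tcw_signature.json"
        sig_out.write_text(json.dumps(sig_report, indent=2) + "\n")
        outputs.append(sig_out)
        report["stages"]["signature"] = sig_report

    if "pamscan" in config.stages and catalogs:
        bg = genome_scan.background_pam_frequency(
            genome, genome_scan.BackgroundSamplingSpec(
                n_samples=config.background_n_samples, seed=config.seed))
        pam_report = {"background": {"fraction": bg.fraction, "se": bg.se,
                                     "n": bg.n_samples}}
        for cid, cat in catalogs.items():
            try:
                res = genome_scan.pam_proximity_fraction(cat, genome, config.pam)
            except ValueError:
                continue
            pam_report[cid] = {"fraction": res.fraction, "n": res.n_evaluated,
                               "n_excluded": res.n_excluded}
        pam_out = outdir / "pam_proximity.json"
        pam_out.write_text(json.dumps(pam_report, indent=2) + "\n")
        outputs.append(pam_out)
        report["stages"]["pamscan"] = pam_report

    if "offtarget" in config.stages and config.offtarget_path and catalogs:
        import pandas as pd
        sites = read_offtarget_table(config.offtarget_path)
        ot_report = {}
        rows = []
        for cid, cat in catalogs.items():
            inter = genome_scan.intersect_offtargets(cat, sites)
            ot_report[cid] = {"total_hits": inter.total, "n_sites": len(sites)}
            for site, n in inter.per_site:
                rows.append((cid, site.chrom, site.start, site.end, site.grna_id,
                             site.mismatches, site.cfd_score, n))
        ot_out = outdir / "offtarget_hits.tsv"
        pd.DataFrame(rows, columns=["clone", "chrom", "start", "end", "gRNA",
                                    "mismatches", "cfd", "n_variants"]
                     ).to_csv(ot_out, sep="\t", index=False)
        outputs.append(ot_out)
        report["stages"]["offtarget"] = ot_report

    if "compare" in config.stages and len(catalogs) >= 2:
        overlap = comparative.overlap_matrix(list(catalogs.values()))
        ov_out = outdir / "overlap_matrix.tsv"
        overlap.to_frame().to_csv(ov_out, sep="\t")
        outputs.append(ov_out)
        cmp_report = {"overlap_matrix": str(ov_out.name)}
        if config.grouping:
            per_clone, groups, excluded = comparative.chromosome_distribution(
                list(catalogs.values()), config.grouping,
                min_total=config.chrom_min_total)
            dist_out = outdir / "chrom_distribution.tsv"
            comparative.distribution_table(per_clone).to_csv(dist_out, sep="\t",
                                                             index=False)
            outputs.append(dist_out)
            cmp_report["excluded_clones"] = excluded
            logger.info("compare: %d clone(s) below the >%d-mutation threshold",
                        len(excluded), config.chrom_min_total)
        report["stages"]["compare"] = cmp_report

    manifest = {
        "seed": config.seed,
        "inputs": {str(p): _sha256(p) for p in
                   [config.genome_path, *config.counts_paths.values(),
                    *config.catalog_paths.values()]
                   + ([config.offtarget_path] if config.offtarget_path else [])},
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    report["manifest"] = manifest
    (outdir / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    return report
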