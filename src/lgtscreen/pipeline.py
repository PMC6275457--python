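"""End-to-end orchestration: simulate -> blob -> lgt -> ctld -> enrich ->
evaluate, as one reproducible run.

The pipeline is a pure function of (config, seed): every stage output is
written to the run directory, hashed, and logged, and re-running with the
same config reproduces identical hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as lio
from .blob import BlobConfig, blob_table, concordance_table, filter_scaffolds
from .ctld import SUMMARY_COLUMNS, cluster_summary, scan_motifs
from .enrichment import RESULT_COLUMNS, domain_enrichment, result_rows
from .errors import ConfigError
from .lgt import REPORT_COLUMNS, ScreenConfig, screen_genome
from .simulate import (
    SimConfig,
    evaluate_ctld,
    evaluate_filter,
    evaluate_lgt,
    generate_dataset,
    generate_domain_tables,
)

log = logging.getLogger("lgtscreen.pipeline")


@dataclass
class RunConfig:
    """Per-stage configuration of one pipeline run."""

    outdir: str = "run"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    blob: BlobConfig = field(default_factory=BlobConfig)
    alpha: float = 0.05
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if not isinstance(raw, dict):
            raise ConfigError("run config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        kw = dict(raw)
        try:
            if "sim" in kw:
                kw["sim"] = SimConfig(**kw["sim"])
            if "screen" in kw:
                kw["screen"] = ScreenConfig(**kw["screen"])
            if "blob" in kw:
                blob = dict(kw["blob"])
                for key in ("host_taxa", "retain_taxa"):
                    if key in blob:
                        blob[key] = frozenset(blob[key])
                if "concordance_ratio_bounds" in blob:
                    blob["concordance_ratio_bounds"] = tuple(
                        blob["concordance_ratio_bounds"])
                kw["blob"] = BlobConfig(**blob)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc
        cfg = cls(**kw)
        if "seed" in raw and "sim" in raw and "seed" in raw["sim"]:
            pass  # explicit per-stage seed wins
        elif "seed" in raw:
            cfg.sim = dataclasses.replace(cfg.sim, seed=cfg.seed)
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage; returns {"outputs": name->path, "hashes": ...,
    "metrics": ...}.  Raises on any stage failure."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=cfg.log_level)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s %(message)s"))
    log.addHandler(handler)
    outputs: dict[str, Path] = {}
    try:
        seed_note = f"seed={cfg.seed}"

        log.info("stage simulate: %s", seed_note)
        data = generate_dataset(cfg.sim)
        datadir = outdir / "inputs"
        outputs.update(data.write(datadir))

        log.info("stage blob")
        table = blob_table(data.scaffolds, data.scaffold_coverage,
                           data.scaffold_hits, data.taxonomy)
        kept, removed = filter_scaffolds(table.records, cfg.blob)
        blob_path = outdir / "blob.tsv"
        lio.write_tsv(table.rows(), blob_path,
                      ["scaffold_id", "length", "gc", "coverage", "taxon",
                       "verdict", "reason"],
                      header_comment=seed_note)
        outputs["blob"] = blob_path

        conc = concordance_table(data.loci, data.gene_coverage,
                                 data.scaffold_coverage, cfg.blob)
        conc_path = outdir / "concordance.tsv"
        lio.write_tsv(conc, conc_path,
                      ["gene_id", "scaffold_id", "gene_cov", "scaffold_cov",
                       "ratio", "concordant"],
                      header_comment=seed_note)
        outputs["concordance"] = conc_path

        log.info("stage lgt")
        report = screen_genome(data.gene_hits, data.taxonomy, data.groups,
                               cfg.screen,
                               genes=list(data.truth.gene_labels))
        lgt_path = outdir / "lgt_report.tsv"
        lio.write_tsv(report.rows(), lgt_path, REPORT_COLUMNS,
                      header_comment=seed_note)
        outputs["lgt_report"] = lgt_path

        log.info("stage ctld")
        profiles = []
        for pid in sorted(data.proteins):
            prof = scan_motifs(pid, data.proteins[pid])
            s, t, n = data.flags[pid]
            prof.secretion_flag, prof.tm_flag, prof.nglyc_flag = s, t, n
            profiles.append(prof)
        summaries = cluster_summary(profiles, data.ctld_clusters)
        ctld_path = outdir / "table1.tsv"
        lio.write_tsv([s.row() for s in summaries], ctld_path,
                      SUMMARY_COLUMNS, header_comment=seed_note)
        outputs["table1"] = ctld_path

        log.info("stage enrich")
        observed, background, spiked = generate_domain_tables(cfg.sim.seed)
        results = domain_enrichment(observed, background, alpha=cfg.alpha)
        enrich_path = outdir / "enrich.tsv"
        lio.write_tsv(result_rows(results), enrich_path, RESULT_COLUMNS,
                      header_comment=seed_note)
        outputs["enrich"] = enrich_path

        log.info("stage evaluate")
        metrics = {
            "seed": cfg.seed,
            "lgt": evaluate_lgt(report, data.truth),
            "filter": evaluate_filter(kept, removed, data.truth,
                                      min_coverage=cfg.blob.min_coverage),
            "ctld": {
                "exact": evaluate_ctld(summaries, data.truth,
                                       data.ctld_clusters)["exact"],
            },
            "concordance_frac": (sum(1 for r in conc if r["concordant"])
                                 / max(1, len(conc))),
            "spiked_domain": spiked,
            "spiked_significant": any(r.domain_id == spiked and r.significant
                                      for r in results),
        }
        metrics_path = outdir / "metrics.json"
        lio.write_json(metrics, metrics_path)
        outputs["metrics"] = metrics_path

        hashes = {name: _sha256(Path(p)) for name, p in sorted(outputs.items())}
        lio.write_json(hashes, outdir / "hashes.json")
        for name, digest in hashes.items():
            log.info("output %s sha256=%s", name, digest)
        return {"outputs": {k: str(v) for k, v in outputs.items()},
                "hashes": hashes, "metrics": metrics}
    finally:
        log.removeHandler(handler)
        handler.close()
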