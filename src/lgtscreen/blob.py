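"""Taxon-annotated GC/coverage ("blob") screening of assembly scaffolds.

Each scaffold is summarised by its GC fraction, mean read depth and a
taxonomic assignment derived from its BLAST hits (per-phylum bit-score sum,
arg-max).  Scaffolds are then removed when they look like host contamination
(assigned to a host phylum), like noise (depth below a floor), or are too
short; everything else, including unassigned "no-hit" scaffolds under the
default policy, is kept.  A companion check compares each gene's read depth
with its parent scaffold's: horizontally transferred genes that are real
genomic residents should match their scaffold's coverage, while hits caused
by an unfiltered contaminant scaffold would not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import ConfigError, TaxonomyError, ValidationError
from .io import BlastHit, CoverageTable, GeneLocus, TaxonomyMap

GC_UNDEFINED = float("nan")

_GC_BASES = frozenset("GCgcSs")          # S = G or C (IUPAC)
_UNAMBIGUOUS = frozenset("ACGTUacgtu") | frozenset("Ss")


@dataclass
class ScaffoldRecord:
    scaffold_id: str
    length: int
    gc: float
    coverage: float
    taxon: str = "no-hit"
    verdict: str = "kept"
    reason: str = "-"

    def __post_init__(self):
        if not (math.isnan(self.gc) or 0.0 <= self.gc <= 1.0):
            raise ValidationError(f"{self.scaffold_id}: gc out of [0,1]")
        if self.coverage < 0:
            raise ValidationError(f"{self.scaffold_id}: negative coverage")


@dataclass(frozen=True)
class BlobConfig:
    """Filtering rules; defaults follow the published screen (host phylum
    Chordata removed, depth floor 3, symmetric two-fold concordance
    window)."""

    host_taxa: frozenset[str] = frozenset({"Chordata"})
    retain_taxa: frozenset[str] = frozenset({"Arthropoda"})
    min_coverage: float = 3.0
    min_scaffold_length: int = 1000
    concordance_ratio_bounds: tuple[float, float] = (0.5, 2.0)
    no_hit_policy: str = "keep"

    def __post_init__(self):
        low, high = self.concordance_ratio_bounds
        if not (low < 1.0 < high):
            raise ConfigError("concordance bounds must straddle 1")
        if self.min_coverage < 0:
            raise ConfigError("min_coverage must be >= 0")
        if self.no_hit_policy not in {"keep", "drop"}:
            raise ConfigError(f"bad no_hit_policy {self.no_hit_policy!r}")


def gc_content(sequence: str) -> float:
    """GC fraction over unambiguous bases, case-insensitive.

    Ns and other ambiguity codes (except S) are excluded from the
    denominator; a sequence of only ambiguous bases returns NaN.
    """
    if not sequence:
        raise ValidationError("empty sequence")
    gc = sum(1 for b in sequence if b in _GC_BASES)
    denom = sum(1 for b in sequence if b in _UNAMBIGUOUS)
    return gc / denom if denom else GC_UNDEFINED


def assign_taxon(hits: Sequence[BlastHit], taxmap: TaxonomyMap) -> str:
    """Phylum with the largest bit-score sum ("bestsum"); lexicographic
    tie-break; no hits -> "no-hit"."""
    if not hits:
        return "no-hit"
    unresolved = [str(h.subject_taxon) for h in hits
                  if h.subject_taxon is None or h.subject_taxon not in taxmap]
    if unresolved:
        raise TaxonomyError(unresolved)
    sums: dict[str, float] = {}
    for h in hits:
        phylum = taxmap.phylum(h.subject_taxon)
        sums[phylum] = sums.get(phylum, 0.0) + h.bitscore
    return min(sums, key=lambda p: (-sums[p], p))


def filter_scaffolds(
    records: Iterable[ScaffoldRecord],
    cfg: BlobConfig,
) -> tuple[list[ScaffoldRecord], list[ScaffoldRecord]]:
    """Partition scaffolds into (kept, removed) with a single primary reason.

    Reasons are evaluated in fixed precedence: host-taxon, then
    low-coverage, then short.  The partition is exact and idempotent.
    """
    kept: list[ScaffoldRecord] = []
    removed: list[ScaffoldRecord] = []
    for rec in records:
        if rec.taxon in cfg.host_taxa:
            rec.verdict, rec.reason = "removed", "host-taxon"
        elif rec.coverage < cfg.min_coverage:
            rec.verdict, rec.reason = "removed", "low-coverage"
        elif rec.length < cfg.min_scaffold_length:
            rec.verdict, rec.reason = "removed", "short"
        elif rec.taxon == "no-hit" and cfg.no_hit_policy == "drop":
            rec.verdict, rec.reason = "removed", "no-hit"
        else:
            rec.verdict, rec.reason = "kept", "-"
        (kept if rec.verdict == "kept" else removed).append(rec)
    return kept, removed


def coverage_concordance(
    gene_cov: float,
    scaffold_cov: float,
    cfg: BlobConfig | None = None,
) -> tuple[float, bool]:
    """Gene/scaffold depth ratio and whether it falls in the concordance
    window (default [0.5, 2.0])."""
    cfg = cfg or BlobConfig()
    if scaffold_cov <= 0:
        raise ValidationError("scaffold coverage must be > 0 for a ratio")
    low, high = cfg.concordance_ratio_bounds
    ratio = gene_cov / scaffold_cov
    return ratio, low <= ratio <= high


def concordance_table(
    loci: Sequence[GeneLocus],
    gene_cov: CoverageTable,
    scaffold_cov: CoverageTable,
    cfg: BlobConfig | None = None,
) -> list[dict]:
    """Per-gene concordance rows, sorted by gene id."""
    cfg = cfg or BlobConfig()
    rows = []
    for locus in sorted(loci, key=lambda l: l.gene_id):
        g = gene_cov.get(locus.gene_id)
        s = scaffold_cov.get(locus.scaffold_id)
        if g is None or s is None:
            rows.append({
                "gene_id": locus.gene_id, "scaffold_id": locus.scaffold_id,
                "gene_cov": g if g is not None else float("nan"),
                "scaffold_cov": s if s is not None else float("nan"),
                "ratio": float("nan"), "concordant": False,
            })
            continue
        ratio, ok = coverage_concordance(g, s, cfg)
        rows.append({
            "gene_id": locus.gene_id, "scaffold_id": locus.scaffold_id,
            "gene_cov": g, "scaffold_cov": s,
            "ratio": ratio, "concordant": ok,
        })
    return rows


@dataclass
class BlobTable:
    """Per-scaffold summary plus the overall means used to position
    candidate genes relative to the bulk of the assembly."""

    records: list[ScaffoldRecord]
    mean_gc: float
    mean_coverage: float
    missing_coverage: list[str] = field(default_factory=list)

    def rows(self) -> list[dict]:
        return [
            {
                "scaffold_id": r.scaffold_id, "length": r.length,
                "gc": r.gc, "coverage": r.coverage, "taxon": r.taxon,
                "verdict": r.verdict, "reason": r.reason,
            }
            for r in self.records
        ]


BLOB_COLUMNS = ["scaffold_id", "length", "gc", "coverage", "taxon",
                "verdict", "reason"]


def blob_table(
    sequences: Mapping[str, str],
    coverage: CoverageTable,
    hits: Sequence[BlastHit],
    taxmap: TaxonomyMap,
) -> BlobTable:
    """Build one ScaffoldRecord per FASTA scaffold (sorted by id).

    Scaffolds without a coverage entry are listed in ``missing_coverage``
    (coverage 0), never silently dropped.  Hit query ids are scaffold ids.
    """
    by_scaffold: dict[str, list[BlastHit]] = {}
    for h in hits:
        by_scaffold.setdefault(h.query_id, []).append(h)

    records: list[ScaffoldRecord] = []
    missing: list[str] = []
    for sid in sorted(sequences):
        seq = sequences[sid]
        cov = coverage.get(sid)
        if cov is None:
            missing.append(sid)
            cov = 0.0
        records.append(ScaffoldRecord(
            scaffold_id=sid,
            length=len(seq),
            gc=gc_content(seq),
            coverage=cov,
            taxon=assign_taxon(by_scaffold.get(sid, ()), taxmap),
        ))
    n = len(records)
    mean_gc = (sum(r.gc for r in records if not math.isnan(r.gc)) /
               max(1, sum(1 for r in records if not math.isnan(r.gc))))
    mean_cov = sum(r.coverage for r in records) / n if n else float("nan")
    if n == 0:
        mean_gc = float("nan")
    return BlobTable(records=records, mean_gc=mean_gc, mean_coverage=mean_cov,
                     missing_coverage=missing)


def blob_plot(table: BlobTable, path) -> None:
    """GC vs log10 coverage scatter coloured by assigned taxon."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    taxa = sorted({r.taxon for r in table.records})
    fig, ax = plt.subplots(figsize=(6, 5))
    for taxon in taxa:
        xs = [r.gc for r in table.records if r.taxon == taxon]
        ys = [math.log10(r.coverage + 1e-9) for r in table.records
              if r.taxon == taxon]
        ax.scatter(xs, ys, s=12, alpha=0.7, label=taxon)
    ax.set_xlabel("GC fraction")
    ax.set_ylabel("log10 mean coverage")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def flag_outliers(table: BlobTable, n_mad: float = 3.0) -> set[str]:
    """Scaffold ids beyond n robust-SD (MAD-based) of the kept population
    in GC or log-coverage; a simple contamination spotlight."""
    import numpy as np

    kept = [r for r in table.records if r.verdict == "kept"]
    pool = kept or table.records
    if not pool:
        return set()
    out: set[str] = set()
    for attr, transform in (("gc", lambda x: x),
                            ("coverage", lambda x: math.log10(x + 1e-9))):
        vals = np.array([transform(getattr(r, attr)) for r in pool])
        med = np.median(vals)
        mad = np.median(np.abs(vals - med))
        sd = 1.4826 * mad if mad > 0 else np.std(vals)
        if sd == 0:
            continue
        for r in table.records:
            if abs(transform(getattr(r, attr)) - med) > n_mad * sd:
                out.add(r.scaffold_id)
    return out
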