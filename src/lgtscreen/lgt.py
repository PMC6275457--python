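"""Lateral-gene-transfer candidate screen from BLAST bit-scores.

The LGT index of a gene is

    h = best non-metazoan bit-score - best metazoan bit-score,

where "best" is taken within each database partition after an E-value gate
and after discarding subjects from the query's own phylum (which emulates
building the metazoan reference database without that phylum).  Candidates
are tiered into nested confidence classes:

    class C:  h >= h_min  and  best_nonmet >= nonmet_bitscore_min
    class B:  C  and  h_orth >= h_min      (h averaged over the orthogroup)
    class A:  B  and  best_met < met_bitscore_classA_max

The original Crisp-style class-A rule additionally required every orthogroup
mate to lack a strong metazoan match; that stricter variant is available via
``strict_crisp_classA`` but is off by default, as it penalises large gene
families in which a single member retains metazoan similarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import ConfigError, ConsistencyError, TaxonomyError
from .io import BlastHit, OrthoGroupSet, TaxonomyMap

CLASS_ORDER = {"A": 0, "B": 1, "C": 2, "none": 3}


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds and switches of the screen.

    Defaults are the published ones: h and h_orth at >= 30 (inclusive),
    best non-metazoan bit-score >= 100, class-A metazoan bit-score
    strictly < 100.  A partition with no surviving hit scores
    ``missing_hit_bitscore`` (0 by default), which keeps h defined.
    """

    h_min: float = 30.0
    nonmet_bitscore_min: float = 100.0
    met_bitscore_classA_max: float = 100.0
    evalue_max: float = 1e-5
    query_phylum: str | None = "Arthropoda"
    missing_hit_bitscore: float = 0.0
    strict_crisp_classA: bool = False
    sum_hsps: bool = False
    h_orth_over: str = "all"  # or "class_c": average only class-C mates

    def __post_init__(self):
        if self.h_min <= 0:
            raise ConfigError("h_min must be > 0")
        if self.nonmet_bitscore_min <= 0:
            raise ConfigError("nonmet_bitscore_min must be > 0")
        if self.evalue_max <= 0:
            raise ConfigError("evalue_max must be > 0")
        if self.h_orth_over not in {"all", "class_c"}:
            raise ConfigError(f"bad h_orth_over {self.h_orth_over!r}")


@dataclass
class GeneScore:
    """Per-gene screen evidence and class call."""

    gene_id: str
    best_met: float
    best_nonmet: float
    h: float
    h_orth: float = float("nan")
    group_id: str | None = None
    lgt_class: str = "none"


@dataclass
class LgtReport:
    """Ordered screen output plus per-class tallies and the config used."""

    scores: list[GeneScore]
    class_counts: dict[str, int]
    config: ScreenConfig

    def genes_in_class(self, cls: str) -> list[str]:
        """Gene ids whose call is at least as specific as *cls* (nested)."""
        rank = CLASS_ORDER[cls]
        return [s.gene_id for s in self.scores
                if CLASS_ORDER[s.lgt_class] <= rank]

    def rows(self) -> list[dict]:
        return [
            {
                "gene_id": s.gene_id,
                "best_met": s.best_met,
                "best_nonmet": s.best_nonmet,
                "h": s.h,
                "h_orth": s.h_orth,
                "group_id": s.group_id if s.group_id is not None else "-",
                "lgt_class": s.lgt_class,
            }
            for s in self.scores
        ]


REPORT_COLUMNS = ["gene_id", "best_met", "best_nonmet", "h", "h_orth",
                  "group_id", "lgt_class"]


# ---------------------------------------------------------------------------


def _best(hits: Iterable[BlastHit], sum_hsps: bool, default: float) -> float:
    """Best bit-score of a partition.

    Per-row maximum by default; with *sum_hsps*, HSP bit-scores are summed
    per subject before taking the best subject.  Ties are irrelevant for the
    score itself; deterministic subject choice uses (bitscore desc, evalue
    asc, subject_id asc).
    """
    hits = list(hits)
    if not hits:
        return default
    if sum_hsps:
        totals: dict[str, float] = {}
        for h in hits:
            totals[h.subject_id] = totals.get(h.subject_id, 0.0) + h.bitscore
        return max(totals.values())
    best = max(hits, key=lambda h: (h.bitscore, -h.evalue, h.subject_id))
    return best.bitscore


def best_scores(
    hits: Sequence[BlastHit],
    taxmap: TaxonomyMap,
    cfg: ScreenConfig,
    genes: Iterable[str] | None = None,
) -> dict[str, tuple[float, float]]:
    """Per-gene (best metazoan, best non-metazoan) bit-scores.

    Hits above the E-value gate are discarded; hits whose subject phylum
    equals ``cfg.query_phylum`` are removed entirely before partitioning.
    Genes listed in *genes* but without surviving hits are reported with
    both bests at ``cfg.missing_hit_bitscore``.
    """
    unresolved = {h.subject_taxon for h in hits
                  if h.subject_taxon is None or h.subject_taxon not in taxmap}
    if unresolved:
        raise TaxonomyError([str(t) for t in unresolved])

    met: dict[str, list[BlastHit]] = {}
    nonmet: dict[str, list[BlastHit]] = {}
    gene_ids: dict[str, None] = dict.fromkeys(genes or ())
    for h in hits:
        gene_ids.setdefault(h.query_id)
        if h.evalue > cfg.evalue_max:
            continue
        rec = taxmap[h.subject_taxon]
        if cfg.query_phylum is not None and rec.phylum == cfg.query_phylum:
            continue
        (met if rec.is_metazoan else nonmet).setdefault(h.query_id, []).append(h)

    out: dict[str, tuple[float, float]] = {}
    for g in gene_ids:
        out[g] = (
            _best(met.get(g, ()), cfg.sum_hsps, cfg.missing_hit_bitscore),
            _best(nonmet.get(g, ()), cfg.sum_hsps, cfg.missing_hit_bitscore),
        )
    return out


def best_scores_partitioned(
    hits_met: Sequence[BlastHit],
    hits_nonmet: Sequence[BlastHit],
    cfg: ScreenConfig,
    genes: Iterable[str] | None = None,
) -> dict[str, tuple[float, float]]:
    """Two-database mode: the metazoan/non-metazoan split was made upstream
    (the query phylum is assumed already excluded from the metazoan set)."""
    gene_ids: dict[str, None] = dict.fromkeys(genes or ())
    met: dict[str, list[BlastHit]] = {}
    nonmet: dict[str, list[BlastHit]] = {}
    for pool, part in ((hits_met, met), (hits_nonmet, nonmet)):
        for h in pool:
            gene_ids.setdefault(h.query_id)
            if h.evalue > cfg.evalue_max:
                continue
            part.setdefault(h.query_id, []).append(h)
    return {
        g: (
            _best(met.get(g, ()), cfg.sum_hsps, cfg.missing_hit_bitscore),
            _best(nonmet.get(g, ()), cfg.sum_hsps, cfg.missing_hit_bitscore),
        )
        for g in gene_ids
    }


def compute_h(best_nonmet: float, best_met: float) -> float:
    """LGT index: best non-metazoan bit-score minus best metazoan bit-score."""
    return best_nonmet - best_met


def compute_h_orth(
    gene_id: str,
    groups: OrthoGroupSet,
    h_by_gene: Mapping[str, float],
) -> float:
    """Mean h over the gene's orthogroup (focal gene included).

    An ungrouped gene is its own singleton group: h_orth = h.
    """
    mates = groups.mates(gene_id)
    missing = [m for m in mates if m not in h_by_gene]
    if missing:
        raise ConsistencyError(
            f"group members without an h value: {', '.join(sorted(missing))}"
        )
    return sum(h_by_gene[m] for m in mates) / len(mates)


def classify_gene(
    score: GeneScore,
    cfg: ScreenConfig,
    group_mates: Sequence[GeneScore] = (),
) -> str:
    """Most specific class among A > B > C > none.

    *group_mates* (focal gene excluded) is consulted only under
    ``strict_crisp_classA``.
    """
    is_c = score.h >= cfg.h_min and score.best_nonmet >= cfg.nonmet_bitscore_min
    if not is_c:
        return "none"
    if not score.h_orth >= cfg.h_min:
        return "C"
    if not score.best_met < cfg.met_bitscore_classA_max:
        return "B"
    if cfg.strict_crisp_classA and any(
        not (m.best_met < cfg.met_bitscore_classA_max) for m in group_mates
    ):
        return "B"
    return "A"


def screen_genome(
    hits: Sequence[BlastHit] | None,
    taxmap: TaxonomyMap | None,
    groups: OrthoGroupSet,
    cfg: ScreenConfig,
    genes: Iterable[str] | None = None,
    hits_met: Sequence[BlastHit] | None = None,
    hits_nonmet: Sequence[BlastHit] | None = None,
) -> LgtReport:
    """Run the full screen and return a deterministic report.

    Either a single hit pool plus taxonomy map, or pre-partitioned
    ``hits_met``/``hits_nonmet`` pools, may be supplied.  Genes are sorted
    by (class rank A > B > C > none, descending h, gene_id).
    """
    if hits is not None:
        if taxmap is None:
            raise ConfigError("single-pool mode requires a taxonomy map")
        bests = best_scores(hits, taxmap, cfg, genes=genes)
    else:
        bests = best_scores_partitioned(hits_met or (), hits_nonmet or (),
                                        cfg, genes=genes)

    # every grouped gene needs an h for the orthogroup mean
    universe = dict.fromkeys(bests)
    for gid in groups.gene_to_group:
        universe.setdefault(gid)
    miss = (cfg.missing_hit_bitscore, cfg.missing_hit_bitscore)
    scores = {
        g: GeneScore(
            gene_id=g,
            best_met=bests.get(g, miss)[0],
            best_nonmet=bests.get(g, miss)[1],
            h=compute_h(bests.get(g, miss)[1], bests.get(g, miss)[0]),
            group_id=groups.group_of(g),
        )
        for g in universe
    }

    h_by_gene = {g: s.h for g, s in scores.items()}
    if cfg.h_orth_over == "all":
        for s in scores.values():
            s.h_orth = compute_h_orth(s.gene_id, groups, h_by_gene)
    else:
        # average only over mates that themselves satisfy the class-C gates
        for s in scores.values():
            mates = [scores[m] for m in groups.mates(s.gene_id)]
            eligible = [m.h for m in mates
                        if m.h >= cfg.h_min
                        and m.best_nonmet >= cfg.nonmet_bitscore_min]
            pool = eligible or [s.h]
            s.h_orth = sum(pool) / len(pool)

    for s in scores.values():
        mates = [scores[m] for m in groups.mates(s.gene_id)
                 if m != s.gene_id]
        s.lgt_class = classify_gene(s, cfg, mates)

    ordered = sorted(
        scores.values(),
        key=lambda s: (CLASS_ORDER[s.lgt_class], -s.h, s.gene_id),
    )
    counts = {c: 0 for c in ("A", "B", "C", "none")}
    for s in ordered:
        counts[s.lgt_class] += 1
    return LgtReport(scores=ordered, class_counts=counts, config=cfg)
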