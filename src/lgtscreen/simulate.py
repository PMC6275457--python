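"""Seeded generators for every pipeline input, with planted ground truth.

The generator emulates the statistical structure the screen assumes rather
than sequence-level realism: native genes have metazoan-dominant BLAST
scores, planted LGT genes have non-metazoan-dominant scores separated by a
guaranteed gap, contaminant scaffolds have displaced GC and coverage, LGT
genes co-cluster in orthogroups, and CTLD-like proteins carry motifs at
exactly controlled counts.  With the default configuration every class
threshold is decidable by construction, so planted-truth recovery is exact;
a "noisy" mode adds Gaussian score overlap for power studies.

All randomness flows through one ``numpy.random.default_rng(seed)``; outputs
are byte-identical across runs for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as lio
from .blob import ScaffoldRecord
from .ctld import MOTIFS
from .errors import ConfigError, ConsistencyError
from .io import BlastHit, CoverageTable, GeneLocus, OrthoGroupSet, TaxonomyMap, TaxonRecord
from .lgt import LgtReport

# fixed taxon palette: label -> (is_metazoan, phylum)
TAXON_PALETTE = {
    "Arthropoda_sp": (True, "Arthropoda"),
    "Chordata_sp": (True, "Chordata"),
    "Actinobacteria_sp": (False, "Actinobacteria"),
    "Proteobacteria_sp": (False, "Proteobacteria"),
    "Ascomycota_sp": (False, "Ascomycota"),
}

# background alphabet excludes P and D so EPN/WND/QPD can only occur where
# planted (each motif needs P or D)
_BG_ALPHABET = np.array(list("ACEFGHIKLMNQRSTVWY"))
_NUC = {True: np.array(list("GC")), False: np.array(list("AT"))}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic genome.

    Score model: native genes draw best_met ~ U(*native_met_range*) with
    best_nonmet = best_met - U(*native_gap_range*); LGT genes draw
    best_nonmet ~ U(*lgt_nonmet_range*) with best_met ~ U(0,
    *lgt_met_max*).  The default gap floor of 40 keeps every class
    threshold decidable.
    """

    seed: int = 0
    n_scaffolds: int = 40
    n_genes: int = 200
    n_lgt: int = 10
    lgt_cluster_size: int = 5
    native_group_size: int = 4
    n_native_groups: int = 20
    host_contam_frac: float = 0.15
    microbial_contam_frac: float = 0.10
    gc_mite: tuple[float, float] = (0.42, 0.02)
    gc_contam: tuple[float, float] = (0.62, 0.03)
    cov_mite: tuple[float, float] = (50.0, 5.0)
    cov_contam: tuple[float, float] = (500.0, 50.0)
    cov_host_contam: tuple[float, float] = (8.0, 2.0)
    scaffold_length: tuple[int, int] = (1500, 5000)
    native_met_range: tuple[float, float] = (150.0, 500.0)
    native_gap_range: tuple[float, float] = (40.0, 100.0)
    lgt_nonmet_range: tuple[float, float] = (150.0, 400.0)
    lgt_met_max: float = 80.0
    noisy: bool = False
    noise_sd: float = 30.0
    ctld_cluster_sizes: tuple[int, ...] = (32, 22, 16, 18)
    motif_rates: tuple[dict, ...] | None = None

    def __post_init__(self):
        if self.n_lgt > self.n_genes:
            raise ConfigError("n_lgt cannot exceed n_genes")
        for frac in (self.host_contam_frac, self.microbial_contam_frac):
            if not 0.0 <= frac <= 1.0:
                raise ConfigError("contaminant fractions must be in [0,1]")
        if self.host_contam_frac + self.microbial_contam_frac >= 1.0:
            raise ConfigError("contaminant fractions must sum to < 1")
        if self.native_met_range[1] <= self.native_met_range[0]:
            raise ConfigError("native_met_range must be increasing")
        if self.lgt_cluster_size < 1:
            raise ConfigError("lgt_cluster_size must be >= 1")


DEFAULT_MOTIF_RATES = (
    {"EPN": 0.2, "WND": 0.05, "QPD": 0.05, "secretion": 0.5, "tm": 0.15,
     "nglyc": 0.2},
    {"EPN": 0.7, "WND": 0.6, "QPD": 0.05, "secretion": 0.65, "tm": 0.0,
     "nglyc": 0.05},
    {"EPN": 0.7, "WND": 0.6, "QPD": 0.0, "secretion": 0.6, "tm": 0.1,
     "nglyc": 0.05},
    {"EPN": 0.1, "WND": 0.1, "QPD": 0.0, "secretion": 0.45, "tm": 0.15,
     "nglyc": 0.2},
)


@dataclass
class TruthTable:
    """Planted labels: gene -> native/lgt, scaffold -> origin, protein ->
    planted motif and flag booleans."""

    gene_labels: dict[str, str]
    scaffold_labels: dict[str, str]
    protein_truth: dict[str, dict[str, bool]]

    def to_json(self) -> dict:
        return {
            "gene_labels": self.gene_labels,
            "scaffold_labels": self.scaffold_labels,
            "protein_truth": self.protein_truth,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "TruthTable":
        return cls(gene_labels=dict(obj["gene_labels"]),
                   scaffold_labels=dict(obj["scaffold_labels"]),
                   protein_truth={k: dict(v)
                                  for k, v in obj["protein_truth"].items()})


@dataclass
class Dataset:
    """In-memory bundle of every pipeline input plus the truth table."""

    config: SimConfig
    scaffolds: dict[str, str]
    loci: list[GeneLocus]
    gene_hits: list[BlastHit]
    scaffold_hits: list[BlastHit]
    taxonomy: TaxonomyMap
    groups: OrthoGroupSet
    scaffold_coverage: CoverageTable
    gene_coverage: CoverageTable
    proteins: dict[str, str]
    flags: dict[str, tuple[bool, bool, bool]]
    ctld_clusters: OrthoGroupSet
    truth: TruthTable

    def write(self, outdir) -> dict[str, Path]:
        """Write the full input bundle; returns name -> path."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "scaffolds": outdir / "scaffolds.fasta",
            "loci": outdir / "loci.bed",
            "gene_hits": outdir / "gene_hits.tsv",
            "scaffold_hits": outdir / "scaffold_hits.tsv",
            "taxonomy": outdir / "taxonomy.tsv",
            "groups": outdir / "groups.txt",
            "scaffold_coverage": outdir / "scaffold_coverage.tsv",
            "gene_coverage": outdir / "gene_coverage.tsv",
            "proteins": outdir / "proteins.fasta",
            "flags": outdir / "flags.tsv",
            "ctld_clusters": outdir / "ctld_clusters.txt",
            "truth": outdir / "truth.json",
        }
        lio.write_fasta(self.scaffolds, paths["scaffolds"])
        lio.write_loci(self.loci, paths["loci"])
        lio.write_blast_tab(self.gene_hits, paths["gene_hits"])
        lio.write_blast_tab(self.scaffold_hits, paths["scaffold_hits"])
        lio.write_taxonomy_map(self.taxonomy, paths["taxonomy"])
        lio.write_orthogroups(self.groups, paths["groups"])
        lio.write_coverage(self.scaffold_coverage, paths["scaffold_coverage"])
        lio.write_coverage(self.gene_coverage, paths["gene_coverage"])
        lio.write_fasta(self.proteins, paths["proteins"])
        lio.write_flags(self.flags, paths["flags"])
        lio.write_orthogroups(self.ctld_clusters, paths["ctld_clusters"])
        lio.write_json(self.truth.to_json(), paths["truth"])
        return paths


def _seq(rng: np.random.Generator, length: int, gc: float) -> str:
    is_gc = rng.random(length) < gc
    bases = np.where(is_gc,
                     _NUC[True][rng.integers(0, 2, length)],
                     _NUC[False][rng.integers(0, 2, length)])
    return "".join(bases)


def generate_dataset(cfg: SimConfig) -> Dataset:
    """Build the full synthetic input bundle; deterministic given cfg.seed."""
    rng = np.random.default_rng(cfg.seed)

    # --- scaffold composition -------------------------------------------
    n_host = round(cfg.n_scaffolds * cfg.host_contam_frac)
    n_micro = round(cfg.n_scaffolds * cfg.microbial_contam_frac)
    n_mite = cfg.n_scaffolds - n_host - n_micro
    if n_mite < 1:
        raise ConfigError("no mite scaffolds left after contamination")

    scaffold_labels: dict[str, str] = {}
    scaffolds: dict[str, str] = {}
    scaffold_cov = CoverageTable()
    scaffold_hits: list[BlastHit] = []
    gene_cov = CoverageTable()

    def cov(mean_sd) -> float:
        return float(max(0.1, rng.normal(*mean_sd)))

    gc_mite = np.clip(rng.normal(*cfg.gc_mite, cfg.n_scaffolds), 0.25, 0.6)
    gc_contam = np.clip(rng.normal(*cfg.gc_contam, cfg.n_scaffolds), 0.4, 0.8)
    lengths = rng.integers(cfg.scaffold_length[0], cfg.scaffold_length[1] + 1,
                           cfg.n_scaffolds)

    kinds = (["mite"] * n_mite + ["host-contaminant"] * n_host
             + ["microbial-contaminant"] * n_micro)
    mite_ids: list[str] = []
    for i, kind in enumerate(kinds):
        sid = f"scaffold{i + 1:04d}"
        scaffold_labels[sid] = kind
        if kind == "mite":
            gc = float(gc_mite[i])
            depth = max(5.0, cov(cfg.cov_mite))
            taxon = "Arthropoda_sp"
            mite_ids.append(sid)
        elif kind == "host-contaminant":
            gc = float(np.clip(rng.normal(0.45, 0.02), 0.3, 0.6))
            depth = cov(cfg.cov_host_contam)
            taxon = "Chordata_sp"
        else:
            gc = float(gc_contam[i])
            depth = cov(cfg.cov_contam)
            taxon = ("Actinobacteria_sp" if rng.random() < 0.5
                     else "Proteobacteria_sp")
        scaffolds[sid] = _seq(rng, int(lengths[i]), gc)
        scaffold_cov[sid] = round(depth, 3)
        bits = float(rng.uniform(300, 800))
        scaffold_hits.append(_hit(sid, f"ref_{taxon}", bits, 1e-60, taxon))
        if kind == "mite" and rng.random() < 0.3:
            # weak secondary hit; bestsum still picks Arthropoda
            weak = ("Chordata_sp" if rng.random() < 0.5 else "Ascomycota_sp")
            scaffold_hits.append(
                _hit(sid, f"ref2_{weak}", float(rng.uniform(40, bits * 0.3)),
                     1e-10, weak))

    # --- genes: placement, scores, hits ---------------------------------
    gene_ids = [f"gene{i + 1:04d}" for i in range(cfg.n_genes)]
    lgt_idx = set(rng.choice(cfg.n_genes, size=cfg.n_lgt, replace=False)
                  .tolist())
    gene_labels = {g: ("lgt" if i in lgt_idx else "native")
                   for i, g in enumerate(gene_ids)}

    loci: list[GeneLocus] = []
    cursor: dict[str, int] = {sid: 100 for sid in mite_ids}
    for i, g in enumerate(gene_ids):
        sid = mite_ids[i % len(mite_ids)]
        start = cursor[sid]
        end = start + 300
        if end > len(scaffolds[sid]):
            # extend the scaffold so the placement stays valid
            scaffolds[sid] = scaffolds[sid] + _seq(rng, end + 100 - len(scaffolds[sid]),
                                                   float(cfg.gc_mite[0]))
        cursor[sid] = end + 100
        strand = "+" if rng.random() < 0.5 else "-"
        loci.append(GeneLocus(g, sid, start, end, strand))
        gene_cov[g] = round(scaffold_cov[sid] * float(rng.uniform(0.9, 1.1)), 3)

    gene_hits: list[BlastHit] = []
    for g in gene_ids:
        if gene_labels[g] == "native":
            best_met = float(rng.uniform(*cfg.native_met_range))
            gap = float(rng.uniform(*cfg.native_gap_range))
            best_nonmet = best_met - gap
            if cfg.noisy:
                best_nonmet = min(best_met,
                                  best_nonmet + float(rng.normal(0, cfg.noise_sd)))
            gene_hits.append(_hit(g, "met_ref", best_met, 1e-80, "Chordata_sp"))
            if best_nonmet > 0:
                nm_tax = ("Proteobacteria_sp" if rng.random() < 0.7
                          else "Ascomycota_sp")
                gene_hits.append(_hit(g, "nonmet_ref", best_nonmet, 1e-40,
                                      nm_tax))
            if rng.random() < 0.3:
                # same-phylum hit, excluded by the screen
                gene_hits.append(_hit(g, "arthro_ref",
                                      best_met + float(rng.uniform(10, 100)),
                                      1e-90, "Arthropoda_sp"))
            if rng.random() < 0.2:
                # decoy above the E-value gate
                gene_hits.append(_hit(g, "decoy_ref",
                                      float(rng.uniform(500, 900)),
                                      1e-3, "Actinobacteria_sp"))
        else:
            best_nonmet = float(rng.uniform(*cfg.lgt_nonmet_range))
            best_met = float(rng.uniform(0, cfg.lgt_met_max))
            tax = ("Actinobacteria_sp" if rng.random() < 0.5
                   else "Proteobacteria_sp")
            gene_hits.append(_hit(g, "lgt_donor", best_nonmet, 1e-70, tax))
            # a second, weaker non-metazoan hit exercises best-of selection
            gene_hits.append(_hit(g, "lgt_donor2",
                                  best_nonmet * float(rng.uniform(0.4, 0.8)),
                                  1e-30, tax))
            if best_met > 5:
                gene_hits.append(_hit(g, "met_weak", best_met, 1e-8,
                                      "Chordata_sp"))

    # --- orthogroups: LGT genes co-cluster ------------------------------
    groups: dict[str, list[str]] = {}
    lgt_genes = [g for g in gene_ids if gene_labels[g] == "lgt"]
    for j in range(0, len(lgt_genes), cfg.lgt_cluster_size):
        chunk = lgt_genes[j:j + cfg.lgt_cluster_size]
        if len(chunk) >= 2:
            groups[f"lgtgrp{j // cfg.lgt_cluster_size + 1}"] = chunk
    natives = [g for g in gene_ids if gene_labels[g] == "native"]
    k = 0
    for j in range(cfg.n_native_groups):
        chunk = natives[k:k + cfg.native_group_size]
        k += cfg.native_group_size
        if len(chunk) >= 2:
            groups[f"natgrp{j + 1}"] = chunk

    # --- taxonomy --------------------------------------------------------
    taxonomy = TaxonomyMap({label: TaxonRecord(*rec)
                            for label, rec in TAXON_PALETTE.items()})

    # --- CTLD proteins, motif planting, flags ----------------------------
    rates = cfg.motif_rates or DEFAULT_MOTIF_RATES
    if len(rates) != len(cfg.ctld_cluster_sizes):
        raise ConfigError("motif_rates must match ctld_cluster_sizes")
    proteins: dict[str, str] = {}
    flags: dict[str, tuple[bool, bool, bool]] = {}
    protein_truth: dict[str, dict[str, bool]] = {}
    ctld_groups: dict[str, list[str]] = {}
    pnum = 0
    for ci, (size, rate) in enumerate(zip(cfg.ctld_cluster_sizes, rates)):
        cid = f"ctldgrp{ci + 1}"
        members: list[str] = []
        # exact planted counts: rate * size rounded, assigned to a random
        # subset so truth is decidable, not merely expected
        planted: dict[str, set[int]] = {}
        for key in (*MOTIFS, "secretion", "tm", "nglyc"):
            count = round(rate.get(key, 0.0) * size)
            planted[key] = set(rng.choice(size, size=count, replace=False)
                               .tolist())
        for j in range(size):
            pid = f"ctld{pnum + 1:03d}"
            pnum += 1
            members.append(pid)
            body = "".join(_BG_ALPHABET[rng.integers(0, len(_BG_ALPHABET),
                                                     150)])
            # plant motifs at disjoint 10-residue slots
            slots = rng.permutation(14)[:len(MOTIFS)]
            for m_i, motif in enumerate(MOTIFS):
                if j in planted[motif]:
                    pos = int(slots[m_i]) * 10 + int(rng.integers(0, 7))
                    body = body[:pos] + motif + body[pos + 3:]
            proteins[pid] = body
            flags[pid] = (j in planted["secretion"], j in planted["tm"],
                          j in planted["nglyc"])
            protein_truth[pid] = {
                "EPN": j in planted["EPN"], "WND": j in planted["WND"],
                "QPD": j in planted["QPD"],
                "secretion": flags[pid][0], "tm": flags[pid][1],
                "nglyc": flags[pid][2],
            }
        ctld_groups[cid] = members

    return Dataset(
        config=cfg,
        scaffolds=scaffolds,
        loci=loci,
        gene_hits=gene_hits,
        scaffold_hits=scaffold_hits,
        taxonomy=taxonomy,
        groups=OrthoGroupSet(groups),
        scaffold_coverage=scaffold_cov,
        gene_coverage=gene_cov,
        proteins=proteins,
        flags=flags,
        ctld_clusters=OrthoGroupSet(ctld_groups),
        truth=TruthTable(gene_labels=gene_labels,
                         scaffold_labels=scaffold_labels,
                         protein_truth=protein_truth),
    )


def _hit(query: str, subject: str, bitscore: float, evalue: float,
         taxon: str) -> BlastHit:
    return BlastHit(
        query_id=query, subject_id=subject,
        percent_identity=50.0, alignment_length=200, mismatches=100,
        gap_opens=1, q_start=1, q_end=200, s_start=1, s_end=200,
        evalue=evalue, bitscore=round(bitscore, 1),
    subject_taxon=taxon)


def generate_domain_tables(
    seed: int,
    n_background: int = 500,
    n_observed: int = 50,
    n_null_domains: int = 200,
    null_rate: float = 0.05,
    spike_background_rate: float = 0.1,
    spike_fold: float = 5.0,
) -> tuple[dict[str, list[str]], dict[str, list[str]], str]:
    """Spike-in design for the enrichment test.

    The observed set is a uniform random subset of the background, so every
    null domain is unenriched by construction; one spiked domain is planted
    in the observed set at *spike_fold* times its background rate.
    Returns (observed, background, spiked_domain_id).
    """
    rng = np.random.default_rng(seed)
    pids = [f"prot{i + 1:04d}" for i in range(n_background)]
    background: dict[str, list[str]] = {p: [] for p in pids}
    observed_ids = sorted(rng.choice(n_background, size=n_observed,
                                     replace=False).tolist())
    observed_set = {pids[i] for i in observed_ids}

    for d in range(n_null_domains):
        dom = f"PFnull{d + 1:04d}"
        carriers = rng.random(n_background) < null_rate
        for i in np.nonzero(carriers)[0]:
            background[pids[i]].append(dom)

    spiked = "PFspike0001"
    p_obs = min(1.0, spike_background_rate * spike_fold)
    for i, pid in enumerate(pids):
        rate = p_obs if pid in observed_set else spike_background_rate
        if rng.random() < rate:
            background[pid].append(spiked)

    observed = {p: list(background[p]) for p in sorted(observed_set)}
    return observed, background, spiked


# ---------------------------------------------------------------------------
# truth evaluation


def evaluate_lgt(report: LgtReport, truth: TruthTable,
                 target_class: str = "A") -> dict:
    """Sensitivity/specificity of class calls against planted labels."""
    known = set(truth.gene_labels)
    stray = [s.gene_id for s in report.scores if s.gene_id not in known]
    if stray:
        raise ConsistencyError("unknown gene id(s) in report: "
                               + ", ".join(sorted(stray)[:5]))
    called = set(report.genes_in_class(target_class))
    pos = {g for g, lab in truth.gene_labels.items() if lab == "lgt"}
    neg = known - pos
    tp = len(called & pos)
    fp = len(called & neg)
    fn = len(pos - called)
    tn = len(neg - called)
    confusion = {}
    for cls in ("A", "B", "C", "none"):
        in_cls = [s.gene_id for s in report.scores if s.lgt_class == cls]
        confusion[cls] = {
            "lgt": sum(1 for g in in_cls if g in pos),
            "native": sum(1 for g in in_cls if g in neg),
        }
    return {
        "sensitivity": tp / len(pos) if pos else 1.0,
        "specificity": tn / len(neg) if neg else 1.0,
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "confusion": confusion,
    }


def evaluate_filter(kept: list[ScaffoldRecord], removed: list[ScaffoldRecord],
                    truth: TruthTable, min_coverage: float = 3.0) -> dict:
    """Contaminant-removal and mite-retention rates against planted
    scaffold origins."""
    known = set(truth.scaffold_labels)
    stray = [r.scaffold_id for r in kept + removed
             if r.scaffold_id not in known]
    if stray:
        raise ConsistencyError("unknown scaffold id(s): "
                               + ", ".join(sorted(stray)[:5]))
    removed_ids = {r.scaffold_id for r in removed}
    host = {s for s, lab in truth.scaffold_labels.items()
            if lab == "host-contaminant"}
    mite_ok = {r.scaffold_id for r in kept + removed
               if truth.scaffold_labels[r.scaffold_id] == "mite"
               and r.coverage >= min_coverage}
    return {
        "host_removed_frac": (len(host & removed_ids) / len(host)
                              if host else 1.0),
        "mite_retained_frac": (len(mite_ok - removed_ids) / len(mite_ok)
                               if mite_ok else 1.0),
        "n_removed": len(removed_ids),
    }


def evaluate_ctld(summaries, truth: TruthTable,
                  clusters: OrthoGroupSet) -> dict:
    """Do the tabulated per-cluster counts match the planted truth?"""
    expected = {}
    for cid, members in clusters.groups.items():
        expected[cid] = {
            key: sum(truth.protein_truth[m][key] for m in members)
            for key in ("EPN", "WND", "QPD", "secretion", "tm", "nglyc")
        }
    mismatches = []
    for s in summaries:
        if s.cluster_id not in expected:
            continue
        for key, want in expected[s.cluster_id].items():
            if s.counts[key] != want:
                mismatches.append((s.cluster_id, key, s.counts[key], want))
    return {"count_mismatches": mismatches, "exact": not mismatches}


def evaluate_against_truth(result, truth: TruthTable, **kw) -> dict:
    """Dispatch on result type (LgtReport, (kept, removed) pair, or
    cluster summaries + clusters)."""
    if isinstance(result, LgtReport):
        return evaluate_lgt(result, truth, **kw)
    if isinstance(result, tuple) and len(result) == 2:
        return evaluate_filter(result[0], result[1], truth, **kw)
    return evaluate_ctld(result, truth, **kw)
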