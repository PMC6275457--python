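"""LGT index computation and A/B/C classification, checked against an
independent brute-force re-derivation of the published rules."""

import random

import pytest

from lgtscreen import (
    OrthoGroupSet,
    ScreenConfig,
    SimConfig,
    best_scores,
    classify_gene,
    compute_h,
    compute_h_orth,
    generate_dataset,
    screen_genome,
)
from lgtscreen.errors import ConsistencyError, TaxonomyError
from lgtscreen.lgt import GeneScore

from conftest import make_hit


# ---------------------------------------------------------------------------
# independent oracle: literal re-application of the class predicates


def brute_force_screen(hits, taxmap, groups, cfg, genes=()):
    """Recompute bests, h, group means and the three class predicates
    from first principles, without the screen's own code paths."""
    genes = sorted({h.query_id for h in hits} | set(groups.gene_to_group)
                   | set(genes))
    best = {}
    for g in genes:
        met, nonmet = [], []
        for h in hits:
            if h.query_id != g or h.evalue > cfg.evalue_max:
                continue
            rec = taxmap[h.subject_taxon]
            if rec.phylum == cfg.query_phylum:
                continue
            (met if rec.is_metazoan else nonmet).append(h.bitscore)
        best[g] = (max(met, default=cfg.missing_hit_bitscore),
                   max(nonmet, default=cfg.missing_hit_bitscore))
    h_val = {g: best[g][1] - best[g][0] for g in genes}
    out = {}
    for g in genes:
        mates = groups.mates(g)
        h_orth = sum(h_val[m] for m in mates) / len(mates)
        bm, bnm = best[g]
        is_c = h_val[g] >= cfg.h_min and bnm >= cfg.nonmet_bitscore_min
        is_b = is_c and h_orth >= cfg.h_min
        is_a = is_b and bm < cfg.met_bitscore_classA_max
        if cfg.strict_crisp_classA:
            is_a = is_a and all(best[m][0] < cfg.met_bitscore_classA_max
                                for m in mates)
        out[g] = "A" if is_a else "B" if is_b else "C" if is_c else "none"
    return out


def random_instance(rng):
    """A small random screening problem (<=50 genes, <=5 groups)."""
    n = rng.randint(2, 50)
    genes = [f"g{i}" for i in range(n)]
    taxa = ["Arthropoda_sp", "Chordata_sp", "Actinobacteria_sp",
            "Proteobacteria_sp", "Ascomycota_sp"]
    hits = []
    for g in genes:
        for j in range(rng.randint(0, 4)):
            hits.append(make_hit(
                g, f"s{j}", round(rng.uniform(0, 400), 1),
                evalue=rng.choice([1e-50, 1e-8, 1e-3]),
                taxon=rng.choice(taxa)))
    shuffled = genes[:]
    rng.shuffle(shuffled)
    groups = {}
    idx = 0
    for gi in range(rng.randint(0, 5)):
        size = rng.randint(2, 6)
        if idx + size > len(shuffled):
            break
        groups[f"grp{gi}"] = shuffled[idx:idx + size]
        idx += size
    return hits, OrthoGroupSet(groups), genes


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_oracle_equivalence_on_random_instances(seed, taxmap):
    """screen_genome matches the literal rule re-application gene-for-gene
    across many random instances, with and without the strict rule."""
    rng = random.Random(seed)
    for rep in range(50):
        hits, groups, genes = random_instance(rng)
        cfg = ScreenConfig(strict_crisp_classA=bool(rep % 2))
        report = screen_genome(hits, taxmap, groups, cfg, genes=genes)
        expected = brute_force_screen(hits, taxmap, groups, cfg, genes)
        got = {s.gene_id: s.lgt_class for s in report.scores}
        assert got == expected


# ---------------------------------------------------------------------------
# unit behaviour


class TestBestScores:
    def test_partition_rules(self, taxmap):
        hits = [
            make_hit("g1", "arth", 500.0, taxon="Arthropoda_sp"),
            make_hit("g1", "chor", 180.0, taxon="Chordata_sp"),
            make_hit("g1", "acti", 250.0, taxon="Actinobacteria_sp"),
        ]
        assert best_scores(hits, taxmap, ScreenConfig())["g1"] == (180.0, 250.0)

    def test_missing_partition_defaults_to_zero(self, taxmap):
        hits = [make_hit("g2", "acti", 120.0, taxon="Actinobacteria_sp")]
        assert best_scores(hits, taxmap, ScreenConfig())["g2"] == (0.0, 120.0)

    def test_evalue_gate(self, taxmap):
        hits = [make_hit("g3", "acti", 300.0, evalue=1e-3,
                         taxon="Actinobacteria_sp")]
        assert best_scores(hits, taxmap, ScreenConfig())["g3"] == (0.0, 0.0)

    def test_unresolvable_taxon_raises(self, taxmap):
        hits = [make_hit("g1", "s", 100.0, taxon="Mystery_sp")]
        with pytest.raises(TaxonomyError, match="Mystery_sp"):
            best_scores(hits, taxmap, ScreenConfig())

    def test_sum_hsps_mode(self, taxmap):
        hits = [make_hit("g1", "acti", 60.0, taxon="Actinobacteria_sp"),
                make_hit("g1", "acti", 50.0, taxon="Actinobacteria_sp"),
                make_hit("g1", "prot", 80.0, taxon="Proteobacteria_sp")]
        assert best_scores(hits, taxmap, ScreenConfig())["g1"][1] == 80.0
        assert best_scores(hits, taxmap,
                           ScreenConfig(sum_hsps=True))["g1"][1] == 110.0


def test_compute_h_is_plain_subtraction():
    assert compute_h(250.0, 180.0) == 70.0
    assert compute_h(42.0, 42.0) == 0.0
    assert compute_h(120.0, 0.0) == 120.0


class TestHOrth:
    def test_group_mean_includes_focal_gene(self):
        groups = OrthoGroupSet({"grp": ["a", "b", "c"]})
        h = {"a": 40.0, "b": 20.0, "c": 60.0}
        assert compute_h_orth("a", groups, h) == 40.0
        assert compute_h_orth("b", groups, h) == 40.0

    def test_singleton_uses_own_h(self):
        groups = OrthoGroupSet({})
        assert compute_h_orth("solo", groups, {"solo": 33.0}) == 33.0

    def test_negative_members_pull_the_mean(self):
        groups = OrthoGroupSet({"grp": ["a", "b"]})
        assert compute_h_orth("a", groups, {"a": 30.0, "b": -10.0}) == 10.0

    def test_missing_member_is_consistency_error(self):
        groups = OrthoGroupSet({"grp": ["a", "b"]})
        with pytest.raises(ConsistencyError):
            compute_h_orth("a", groups, {"a": 30.0})


class TestClassify:
    cfg = ScreenConfig()

    def score(self, h, nonmet, met, h_orth):
        return GeneScore("g", best_met=met, best_nonmet=nonmet, h=h,
                         h_orth=h_orth)

    def test_class_a(self):
        assert classify_gene(self.score(35, 120, 85, 32), self.cfg) == "A"

    def test_strong_metazoan_match_demotes_to_b(self):
        assert classify_gene(self.score(35, 120, 110, 32), self.cfg) == "B"

    def test_thresholds_inclusive_except_classa_met(self):
        # exactly at every inclusive bound, met just under the strict bound
        assert classify_gene(self.score(30, 100, 99, 30), self.cfg) == "A"
        assert classify_gene(self.score(30, 100, 100, 30), self.cfg) == "B"
        assert classify_gene(self.score(29.9, 500, 0, 50), self.cfg) == "none"

    def test_low_h_orth_stops_at_c(self):
        assert classify_gene(self.score(35, 120, 85, 29.9), self.cfg) == "C"

    def test_strict_rule_consults_group_mates(self):
        strict = ScreenConfig(strict_crisp_classA=True)
        mate_ok = GeneScore("m1", best_met=50, best_nonmet=200, h=150,
                            h_orth=90)
        mate_bad = GeneScore("m2", best_met=150, best_nonmet=200, h=50,
                             h_orth=90)
        s = self.score(35, 120, 85, 32)
        assert classify_gene(s, strict, [mate_ok]) == "A"
        assert classify_gene(s, strict, [mate_ok, mate_bad]) == "B"


class TestScreenGenome:
    def test_planted_lgt_in_native_group_stops_at_c(self, taxmap):
        """One LGT-like gene clustered with three natives: the 4-member
        group mean of (160, -50, -60, -70)/4 = -5 < 30 blocks class B."""
        hits = [make_hit("lgt1", "d", 160.0, taxon="Actinobacteria_sp")]
        for i, gap in enumerate((50, 60, 70)):
            hits.append(make_hit(f"nat{i}", "m", 200.0, taxon="Chordata_sp"))
            hits.append(make_hit(f"nat{i}", "d", 200.0 - gap,
                                 taxon="Proteobacteria_sp"))
        groups = OrthoGroupSet({"grp": ["lgt1", "nat0", "nat1", "nat2"]})
        report = screen_genome(hits, taxmap, groups, ScreenConfig())
        by_id = {s.gene_id: s for s in report.scores}
        assert by_id["lgt1"].h == 160.0
        assert by_id["lgt1"].h_orth == pytest.approx(-5.0)
        assert by_id["lgt1"].lgt_class == "C"

    def test_no_hits_means_no_candidates(self, taxmap):
        report = screen_genome([], taxmap, OrthoGroupSet({}), ScreenConfig(),
                               genes=["g1", "g2"])
        assert all(s.lgt_class == "none" for s in report.scores)

    def test_report_sorted_and_counts_consistent(self, default_dataset):
        d = default_dataset
        report = screen_genome(d.gene_hits, d.taxonomy, d.groups,
                               ScreenConfig(),
                               genes=list(d.truth.gene_labels))
        ranks = [("A", "B", "C", "none").index(s.lgt_class)
                 for s in report.scores]
        assert ranks == sorted(ranks)
        assert sum(report.class_counts.values()) == len(report.scores)
        assert len({s.gene_id for s in report.scores}) == len(report.scores)


# ---------------------------------------------------------------------------
# invariants


def _report_classes(dataset, cfg):
    report = screen_genome(dataset.gene_hits, dataset.taxonomy,
                           dataset.groups, cfg,
                           genes=list(dataset.truth.gene_labels))
    return report


@pytest.mark.parametrize("seed", range(8))
def test_class_nesting_and_strict_subset(seed):
    """{A} <= {B} <= {C}, and the strict-Crisp class-A set is a subset of
    the default class-A set, on seeded synthetic genomes."""
    data = generate_dataset(SimConfig(seed=seed, n_genes=60, n_scaffolds=15,
                                      n_lgt=6, lgt_cluster_size=3))
    report = _report_classes(data, ScreenConfig())
    a, b, c = (set(report.genes_in_class(k)) for k in "ABC")
    assert a <= b <= c
    strict = _report_classes(data, ScreenConfig(strict_crisp_classA=True))
    assert set(strict.genes_in_class("A")) <= a


def test_swapping_partitions_negates_h(taxmap):
    """Flipping every subject's metazoan flag negates each gene's h."""
    rng = random.Random(7)
    hits, groups, genes = random_instance(rng)
    from lgtscreen.io import TaxonomyMap, TaxonRecord
    flipped = TaxonomyMap({
        label: TaxonRecord(not rec.is_metazoan,
                           rec.phylum if not rec.is_metazoan else rec.phylum)
        for label, rec in taxmap.items()
    })
    cfg = ScreenConfig(query_phylum=None)
    fwd = screen_genome(hits, taxmap, groups, cfg, genes=genes)
    rev = screen_genome(hits, flipped, groups, cfg, genes=genes)
    h_fwd = {s.gene_id: s.h for s in fwd.scores}
    h_rev = {s.gene_id: s.h for s in rev.scores}
    assert all(h_fwd[g] == -h_rev[g] for g in h_fwd)


def test_raising_h_min_never_adds_candidates(default_dataset):
    d = default_dataset
    lax = _report_classes(d, ScreenConfig(h_min=30.0))
    for h_min in (50.0, 100.0, 200.0):
        tight = _report_classes(d, ScreenConfig(h_min=h_min))
        for cls in "ABC":
            assert (set(tight.genes_in_class(cls))
                    <= set(lax.genes_in_class(cls)))
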