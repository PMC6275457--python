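"""GC/coverage blob screening, scaffold filtering and coverage concordance."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lgtscreen import (
    BlobConfig,
    ScaffoldRecord,
    SimConfig,
    assign_taxon,
    blob_table,
    coverage_concordance,
    filter_scaffolds,
    gc_content,
    generate_dataset,
)
from lgtscreen.blob import concordance_table, flag_outliers
from lgtscreen.errors import ValidationError
from lgtscreen.simulate import evaluate_filter

from conftest import make_hit


class TestGcContent:
    def test_direct_counts(self):
        assert gc_content("ATGC") == 0.5
        assert gc_content("GGCC") == 1.0

    def test_ambiguous_bases_excluded_from_denominator(self):
        assert gc_content("ATNNGC") == 0.5

    def test_all_ambiguous_is_undefined(self):
        assert math.isnan(gc_content("NNNN"))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            gc_content("")

    @given(st.text(alphabet="ACGTN", min_size=1, max_size=200))
    @settings(max_examples=60, deadline=None)
    def test_case_and_reverse_complement_invariance(self, seq):
        comp = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}
        rc = "".join(comp[b] for b in reversed(seq))
        a, b, c = gc_content(seq), gc_content(seq.lower()), gc_content(rc)
        if math.isnan(a):
            assert math.isnan(b) and math.isnan(c)
        else:
            assert a == b == pytest.approx(c)


class TestAssignTaxon:
    def test_bestsum_beats_single_best_hit(self, taxmap):
        hits = [make_hit("s1", "c1", 300.0, taxon="Chordata_sp"),
                make_hit("s1", "c2", 200.0, taxon="Chordata_sp"),
                make_hit("s1", "a1", 450.0, taxon="Arthropoda_sp")]
        assert assign_taxon(hits, taxmap) == "Chordata"

    def test_no_hits(self, taxmap):
        assert assign_taxon([], taxmap) == "no-hit"

    def test_single_hit(self, taxmap):
        hits = [make_hit("s1", "x", 90.0, taxon="Actinobacteria_sp")]
        assert assign_taxon(hits, taxmap) == "Actinobacteria"

    def test_tie_broken_lexicographically(self, taxmap):
        hits = [make_hit("s1", "x", 100.0, taxon="Proteobacteria_sp"),
                make_hit("s1", "y", 100.0, taxon="Actinobacteria_sp")]
        assert assign_taxon(hits, taxmap) == "Actinobacteria"


def rec(sid="s", length=2000, gc=0.4, coverage=10.0, taxon="Arthropoda"):
    return ScaffoldRecord(scaffold_id=sid, length=length, gc=gc,
                          coverage=coverage, taxon=taxon)


class TestFilterScaffolds:
    cfg = BlobConfig()

    def test_host_taxon_removed_despite_good_coverage(self):
        kept, removed = filter_scaffolds(
            [rec(taxon="Chordata", coverage=50, length=5000)], self.cfg)
        assert not kept and removed[0].reason == "host-taxon"

    def test_low_coverage_removed(self):
        kept, removed = filter_scaffolds([rec(coverage=2.9)], self.cfg)
        assert removed[0].reason == "low-coverage"

    def test_coverage_exactly_at_floor_kept(self):
        kept, removed = filter_scaffolds([rec(coverage=3.0)], self.cfg)
        assert kept and not removed

    def test_short_scaffold_removed(self):
        kept, removed = filter_scaffolds([rec(length=999)], self.cfg)
        assert removed[0].reason == "short"

    def test_reason_precedence_host_before_coverage_before_length(self):
        (_, removed) = filter_scaffolds(
            [rec(taxon="Chordata", coverage=1.0, length=10)], self.cfg)
        assert removed[0].reason == "host-taxon"
        (_, removed) = filter_scaffolds([rec(coverage=1.0, length=10)],
                                        self.cfg)
        assert removed[0].reason == "low-coverage"

    def test_no_hit_policy(self):
        keep_cfg = BlobConfig()
        drop_cfg = BlobConfig(no_hit_policy="drop")
        kept, _ = filter_scaffolds([rec(taxon="no-hit")], keep_cfg)
        assert kept
        _, removed = filter_scaffolds([rec(taxon="no-hit")], drop_cfg)
        assert removed

    def test_exact_partition_and_idempotence(self):
        records = [rec(sid=f"s{i}", coverage=c, taxon=t, length=l)
                   for i, (c, t, l) in enumerate([
                       (50, "Chordata", 5000), (2, "Arthropoda", 5000),
                       (10, "Arthropoda", 500), (10, "no-hit", 2000),
                       (10, "Arthropoda", 2000)])]
        kept, removed = filter_scaffolds(records, self.cfg)
        assert len(kept) + len(removed) == len(records)
        assert {r.scaffold_id for r in kept}.isdisjoint(
            {r.scaffold_id for r in removed})
        kept2, removed2 = filter_scaffolds(records, self.cfg)
        assert [r.scaffold_id for r in kept2] == [r.scaffold_id for r in kept]
        assert [r.reason for r in removed2] == [r.reason for r in removed]


class TestConcordance:
    def test_similar_coverages_are_concordant(self):
        ratio, ok = coverage_concordance(50.0, 52.0)
        assert ratio == pytest.approx(50 / 52)
        assert ok

    def test_displaced_gene_coverage_is_discordant(self):
        ratio, ok = coverage_concordance(5.0, 100.0)
        assert ratio == 0.05 and not ok

    def test_identity_ratio(self):
        assert coverage_concordance(37.0, 37.0) == (1.0, True)

    def test_zero_scaffold_coverage_rejected(self):
        with pytest.raises(ValidationError):
            coverage_concordance(5.0, 0.0)

    def test_bounds_inclusive(self):
        assert coverage_concordance(1.0, 2.0)[1]
        assert coverage_concordance(2.0, 1.0)[1]
        assert not coverage_concordance(2.01, 1.0)[1]


class TestBlobTable:
    def test_means_match_hand_computation(self, taxmap):
        seqs = {"s1": "ATGC" * 100, "s2": "GGCC" * 100, "s3": "AATT" * 100}
        cov = {"s1": 10.0, "s2": 20.0, "s3": 30.0}
        table = blob_table(seqs, cov, [], taxmap)
        assert len(table.records) == 3
        assert table.mean_gc == pytest.approx((0.5 + 1.0 + 0.0) / 3)
        assert table.mean_coverage == pytest.approx(20.0)
        assert all(r.taxon == "no-hit" for r in table.records)

    def test_empty_inputs_give_empty_table(self, taxmap):
        table = blob_table({}, {}, [], taxmap)
        assert table.records == []

    def test_missing_coverage_reported_not_dropped(self, taxmap):
        table = blob_table({"s1": "ATGC"}, {}, [], taxmap)
        assert table.missing_coverage == ["s1"]
        assert table.records[0].coverage == 0.0

    def test_contaminants_are_gc_coverage_outliers(self, taxmap):
        """Planted microbial contaminants (GC ~0.62, cov ~500) sit beyond
        3 robust-SD of the kept mite population (GC ~0.42, cov ~50)."""
        data = generate_dataset(SimConfig(seed=2))
        table = blob_table(data.scaffolds, data.scaffold_coverage,
                           data.scaffold_hits, data.taxonomy)
        filter_scaffolds(table.records, BlobConfig())
        outliers = flag_outliers(table)
        microbial = {s for s, lab in data.truth.scaffold_labels.items()
                     if lab == "microbial-contaminant"}
        assert microbial <= outliers


def test_planted_contaminant_removal_and_mite_retention(default_dataset):
    """All Chordata-contaminant scaffolds are removed and every mite
    scaffold with coverage >= 3 survives the published filter rules."""
    d = default_dataset
    table = blob_table(d.scaffolds, d.scaffold_coverage, d.scaffold_hits,
                       d.taxonomy)
    kept, removed = filter_scaffolds(table.records, BlobConfig())
    metrics = evaluate_filter(kept, removed, d.truth)
    assert metrics["host_removed_frac"] == 1.0
    assert metrics["mite_retained_frac"] == 1.0


def test_concordance_table_on_generated_genes(default_dataset):
    """Generated gene depths track their parent scaffold within the
    two-fold window."""
    d = default_dataset
    rows = concordance_table(d.loci, d.gene_coverage, d.scaffold_coverage)
    assert len(rows) == len(d.loci)
    assert all(r["concordant"] for r in rows)
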