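# Methods

## The screen

The package implements a bit-score comparative screen for lateral gene
transfer candidates. Its premise: a gene that entered an animal genome
from a microbial donor will align better to non-metazoan proteins than to
metazoan ones, and the difference of the two best BLASTP bit-scores —
`h = B_nonmet − B_met` — quantifies that asymmetry on a scale that is
roughly independent of database size. Hits from the query's own phylum are
excluded before partitioning (they would trivially dominate `B_met` for
any gene, transferred or not); this is implemented as a filter on a single
taxon-annotated hit pool, which is equivalent to the two-database design
(separate metazoan-minus-own-phylum and non-metazoan databases) that the
screen historically used, and that mode is also supported directly via
pre-partitioned hit files.

Classes are nested: class C demands `h ≥ 30` and `B_nonmet ≥ 100`
(both inclusive); class B adds `h_orth ≥ 30`, the mean `h` over the
gene's OrthoMCL cluster with the focal gene included (a singleton's
`h_orth` is its own `h`); class A adds `B_met < 100` (strict). The
classic stricter class-A rule — no cluster member may have `B_met ≥ 100`
— is available as `strict_crisp_classA` but off by default: in a large
cluster a single member with residual metazoan similarity would veto
every other member, which is too blunt for expanded gene families. By
construction the strict class-A set is a subset of the default one, a
property the tests assert.

Assumptions worth making explicit: the screen sees similarity, not
phylogeny — a gene lost in most metazoans but retained in the query
lineage, or a contaminant sequence that survived assembly filtering, will
score like an LGT. The blob screen and the coverage-concordance check
below exist precisely to discharge the contamination alternative; true
phylogenetic confirmation (tree building) is out of scope.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `h_min` | 30 (bit-score units) | class C/B index floor |
| `nonmet_bitscore_min` | 100 | minimum best non-metazoan score |
| `met_bitscore_classA_max` | 100 | strict upper bound on `B_met` for class A |
| `evalue_max` | 1e-5 | hit E-value gate, applied before partitioning |
| `query_phylum` | Arthropoda | phylum removed from the hit pool |
| `missing_hit_bitscore` | 0 | score of an empty partition |

An empty partition scores 0 so `h` stays defined; that convention makes a
gene with only non-metazoan hits maximally LGT-like (`h = B_nonmet`),
which is the intended reading. The E-value gate is configurable because
the screen's own definition does not fix one; 1e-5 matches the BLASTP
practice used elsewhere in this kind of annotation work. "Best" means the
maximum single-row bit-score; a `sum_hsps` switch instead sums HSPs per
subject before taking the best subject, for users whose pipelines score
split alignments that way. `h_orth` averages over all cluster members;
`h_orth_over="class_c"` restricts the mean to members that themselves
pass the class-C gates, the other defensible reading.

## Blob screening

Scaffold taxon assignment sums bit-scores per phylum over the scaffold's
hits and takes the arg-max (ties broken lexicographically) — the
"bestsum" rule familiar from blob-plot tooling. Removal reasons are
evaluated in fixed precedence — host taxon, then coverage < 3, then
length — so each removed scaffold carries exactly one primary reason and
reports are deterministic. Scaffolds with no hits are kept by default
(filtering is by stated taxa only); `no_hit_policy="drop"` inverts that.
GC content counts G, C and the IUPAC code S over unambiguous bases only,
making it invariant to case and reverse complement; an all-ambiguous
sequence yields NaN rather than a fake 0. The length floor defaults to
1000 bp and is set to 500 bp for reassembled-from-filtered-reads style
assemblies; both appear in practice and the choice is a config field.

Gene-vs-scaffold coverage concordance uses the ratio
`gene_depth / scaffold_depth` with a symmetric two-fold window
`[0.5, 2.0]` as the default meaning of "very similar"; the bounds are
configurable. The screen's logic: a transferred gene physically resident
on a mite scaffold must have been sequenced at the scaffold's depth,
whereas an annotation artefact living on an unrecognised contaminant
scaffold would not.

## CTLD tables

Motif search is exact, literal and case-insensitive (EPN, WND, QPD), with
optional restriction to annotated domain intervals; no degenerate
PROSITE-style patterns are used because the original tabulation searched
literal tripeptides. Counting is per protein, not per domain copy.
Secretion, transmembrane and N-glycosylation calls come from external
predictors (SecretomeP, TMHMM, NetNGlyc class tools) and enter as a
boolean flags TSV — re-implementing those predictors is out of scope.
Percentage cells round half-away-from-zero at one decimal, the convention
that reproduces published cells such as 1/16 → "6.3" (6.25) and
6/32 → "18.8" (18.75); zero counts print as a bare "0".

## Domain enrichment

The test is the one-sided hypergeometric upper tail `P(X ≥ k)` for `k`
observed carriers among `n` observed proteins, against `K` carriers in a
background of `N` (computed via `scipy.stats.hypergeom.sf`, which works
in log space; the acceptance suite checks it against exhaustive
enumeration over every design with `N ≤ 25`). Only enrichment is tested,
not depletion. P values across domains are BH step-up adjusted
(statsmodels) and significance is declared on the adjusted value at
`alpha = 0.05` — the conservative reading of "BH-corrected, significant
at P < 0.05"; `threshold_on="p"` restores raw-P thresholding. A
≥2-unique-peptides support filter, applied before counting, mirrors
proteomics practice where single-peptide identifications are unreliable.

## Synthetic data: what it emulates and what it does not

The generator produces the statistical structure the screen assumes, not
realistic sequences. Native genes draw `B_met ~ U(150, 500)` with
`B_nonmet = B_met − U(40, 100)`; LGT genes draw `B_nonmet ~ U(150, 400)`
with `B_met ~ U(0, 80)`. The guaranteed gap of ≥ 40 keeps every planted
gene on a decidable side of every threshold, so default-condition
recovery is exactly sensitivity = specificity = 1 and any deviation is a
bug, not noise. The default genome has 200 genes on 40 scaffolds with 10
LGT genes co-clustered in groups of 5 (echoing the multi-member LGT
clusters real screens report); 15% of scaffolds are host (Chordata-hit)
contaminants and 10% microbial contaminants with displaced GC (~0.62 vs
~0.42) and coverage (~500× vs ~50×). Per-gene depth is the parent
scaffold's depth times `U(0.9, 1.1)`, inside the two-fold concordance
window by construction. CTLD proteins are built over an alphabet lacking
P and D, so EPN/WND/QPD occur only where planted, and planted counts are
exact (`round(rate × size)` members per cluster), not Bernoulli draws. A
`noisy` mode adds Gaussian overlap to the native non-metazoan scores
(capped so `h_native ≤ 0`) for power-curve work.

Consequences for interpretation: passing tests show the rules are
implemented exactly and recover planted structure; they do not show that
real BLAST score distributions separate this cleanly (they do not), nor
do they validate taxon assignment against real database noise. Scale is
also deliberately modest — tens of scaffolds, hundreds of genes — chosen
as the smallest sizes at which every code path (grouping, contamination,
both contaminant kinds, all four CTLD clusters) is exercised.

## Numerical and design choices

- All randomness flows through one `numpy.random.default_rng(seed)`;
  iteration orders are fixed (sorted ids, insertion-ordered dicts), so
  outputs are byte-identical across runs and platforms.
- Report sorting: genes by (class rank A>B>C>none, descending `h`,
  gene id); best-hit tie-break by (bit-score desc, E-value asc, subject
  id asc).
- Numeric serialisation uses `repr`, with integral floats printed as
  integers, so write → read → write round-trips byte-identically.
- Coordinates are 0-based half-open internally; BED is native, GFF3 is
  converted on read.
- Degenerate inputs: empty hit pools give all-`none` reports; an empty
  scaffold set gives an empty blob table with NaN means; a scaffold
  missing coverage is reported in a gap list (coverage 0), never
  silently dropped; `k = 0` returns tail probability 1 exactly.
- The pipeline (`run_pipeline`) is a pure function of (config, seed):
  stage outputs are hashed (SHA-256) and logged, and the hashes are part
  of the report bundle.

## Known limitations

- Filtering operates at scaffold level; extracting the underlying reads
  for reassembly is left to the user.
- Taxon assignment needs a user-supplied taxonomy map; there is no live
  NCBI taxonomy resolution.
- The enrichment module tests presence/absence; domain copy number and
  abundance-weighted designs are out of scope.
- No phylogenetic confirmation of candidates, by design.
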