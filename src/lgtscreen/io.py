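"""Readers and writers for every external file the pipeline touches.

All tables are UTF-8 and tab-separated.  Coordinates are 0-based half-open
internally: BED is consumed natively, GFF3 (1-based closed) is converted on
read.  Report writers use a fixed, documented column order so that
write -> read -> write round-trips byte-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    ConsistencyError,
    DialectError,
    ParseError,
    SchemaError,
    TaxonomyError,
    ValidationError,
)

# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class BlastHit:
    """One query-subject alignment row of BLAST tabular output (outfmt 6)."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float
    subject_taxon: str | None = None

    def __post_init__(self):
        if not self.query_id:
            raise ValidationError("query_id must be nonempty")
        if self.bitscore < 0:
            raise ValidationError(f"bitscore must be >= 0, got {self.bitscore}")
        if self.evalue < 0:
            raise ValidationError(f"evalue must be >= 0, got {self.evalue}")


@dataclass(frozen=True)
class TaxonRecord:
    is_metazoan: bool
    phylum: str

    def __post_init__(self):
        if self.is_metazoan and not self.phylum:
            raise ValidationError("metazoan taxon record requires a phylum")


class TaxonomyMap:
    """Maps subject taxon labels to (is_metazoan, phylum)."""

    def __init__(self, records: Mapping[str, TaxonRecord]):
        self._records = dict(records)

    def __contains__(self, label: str) -> bool:
        return label in self._records

    def __len__(self) -> int:
        return len(self._records)

    def __getitem__(self, label: str) -> TaxonRecord:
        try:
            return self._records[label]
        except KeyError:
            raise TaxonomyError([label]) from None

    def is_metazoan(self, label: str) -> bool:
        return self[label].is_metazoan

    def phylum(self, label: str) -> str:
        return self[label].phylum

    def items(self):
        return self._records.items()


class OrthoGroupSet:
    """OrthoMCL-style clusters with a gene -> group reverse index.

    A gene belongs to at most one group; genes absent from every group are
    implicit singletons.
    """

    def __init__(self, groups: Mapping[str, Iterable[str]]):
        self.groups: dict[str, tuple[str, ...]] = {}
        self.gene_to_group: dict[str, str] = {}
        for gid, members in groups.items():
            members = tuple(members)
            if len(members) != len(set(members)):
                raise ConsistencyError(f"duplicate member within group {gid}")
            for m in members:
                if m in self.gene_to_group:
                    raise ConsistencyError(
                        f"gene {m} appears in groups "
                        f"{self.gene_to_group[m]} and {gid}"
                    )
                self.gene_to_group[m] = gid
            self.groups[gid] = members

    def __len__(self) -> int:
        return len(self.groups)

    def group_of(self, gene_id: str) -> str | None:
        return self.gene_to_group.get(gene_id)

    def members(self, group_id: str) -> tuple[str, ...]:
        return self.groups[group_id]

    def mates(self, gene_id: str) -> tuple[str, ...]:
        """All members of the gene's group, the gene itself included."""
        gid = self.group_of(gene_id)
        return (gene_id,) if gid is None else self.groups[gid]


@dataclass(frozen=True)
class GeneLocus:
    """A gene placement on a scaffold, 0-based half-open."""

    gene_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"{self.gene_id}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValidationError(f"{self.gene_id}: bad strand {self.strand!r}")


class CoverageTable(dict):
    """feature_id -> mean read depth (>= 0)."""

    def __setitem__(self, key: str, value: float):
        if value < 0:
            raise ValidationError(f"negative coverage for {key}: {value}")
        super().__setitem__(key, float(value))


# ---------------------------------------------------------------------------
# BLAST tabular

_BLAST12 = 12
_BLAST13 = 13


def read_blast_tab(path, dialect: str = "12col") -> list[BlastHit]:
    """Parse BLAST outfmt-6 tabular output.

    dialect "12col" is the standard qseqid..bitscore layout; "13col" expects
    a trailing subject-taxon column (e.g. staxids or a phylum label).
    Rows are returned in file order; comment lines (#) are skipped.
    """
    want = {"12col": _BLAST12, "13col": _BLAST13}.get(dialect)
    if want is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    hits: list[BlastHit] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != want:
                raise DialectError(
                    f"expected {want} tab-separated fields, got {len(fields)}",
                    path=path,
                    line=lineno,
                )
            try:
                hit = BlastHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    alignment_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                    subject_taxon=fields[12] if want == _BLAST13 else None,
                )
            except (ValueError, ValidationError) as exc:
                raise ParseError(str(exc), path=path, line=lineno) from exc
            hits.append(hit)
    return hits


def write_blast_tab(hits: Iterable[BlastHit], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for h in hits:
            row = [
                h.query_id,
                h.subject_id,
                _fmt(h.percent_identity),
                str(h.alignment_length),
                str(h.mismatches),
                str(h.gap_opens),
                str(h.q_start),
                str(h.q_end),
                str(h.s_start),
                str(h.s_end),
                _fmt(h.evalue),
                _fmt(h.bitscore),
            ]
            if h.subject_taxon is not None:
                row.append(h.subject_taxon)
            fh.write("\t".join(row) + "\n")


def _fmt(x: float) -> str:
    """Stable numeric formatting: integers lose the trailing .0."""
    return repr(int(x)) if float(x) == int(x) and abs(x) < 1e15 else repr(float(x))


# ---------------------------------------------------------------------------
# OrthoMCL groups


def read_orthogroups(path, strip_species_prefix: bool = True,
                     delimiter: str = "|") -> OrthoGroupSet:
    """Parse an OrthoMCL groups.txt: ``group_id: member member ...``.

    Members carrying ``species|gene`` prefixes are stripped to the bare gene
    id when *strip_species_prefix* is set.
    """
    groups: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise ParseError("missing ':' separator", path=path, line=lineno)
            gid, _, rest = line.partition(":")
            gid = gid.strip()
            members = rest.split()
            if not gid or not members:
                raise ParseError("empty group line", path=path, line=lineno)
            if strip_species_prefix:
                members = [m.split(delimiter, 1)[-1] for m in members]
            if gid in groups:
                raise ParseError(f"group {gid} defined twice", path=path,
                                 line=lineno)
            groups[gid] = members
    return OrthoGroupSet(groups)


def write_orthogroups(groups: OrthoGroupSet, path, species: str | None = None,
                      delimiter: str = "|") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gid in sorted(groups.groups):
            members = groups.groups[gid]
            if species:
                members = [f"{species}{delimiter}{m}" for m in members]
            fh.write(f"{gid}: " + " ".join(members) + "\n")


# ---------------------------------------------------------------------------
# taxonomy / coverage / loci / flags tables

TAXONOMY_COLUMNS = ("taxon", "is_metazoan", "phylum")

_BOOL = {"true": True, "false": False, "1": True, "0": False,
         "yes": True, "no": False}


def _parse_bool(text: str, path, lineno: int) -> bool:
    try:
        return _BOOL[text.strip().lower()]
    except KeyError:
        raise ParseError(f"not a boolean: {text!r}", path=path,
                         line=lineno) from None


def read_taxonomy_map(path) -> TaxonomyMap:
    """Headered 3-column TSV: taxon, is_metazoan, phylum."""
    records: dict[str, TaxonRecord] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(h.strip() for h in header) != TAXONOMY_COLUMNS:
            raise SchemaError(
                f"taxonomy map requires columns {TAXONOMY_COLUMNS}, "
                f"got {tuple(header)}"
            )
        for lineno, raw in enumerate(fh, 2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError("expected 3 fields", path=path, line=lineno)
            label, met, phylum = fields
            if label in records:
                raise ConsistencyError(f"taxon {label} mapped twice")
            records[label] = TaxonRecord(_parse_bool(met, path, lineno),
                                         phylum.strip())
    return TaxonomyMap(records)


def write_taxonomy_map(taxmap: TaxonomyMap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(TAXONOMY_COLUMNS) + "\n")
        for label, rec in sorted(taxmap.items()):
            fh.write(f"{label}\t{'true' if rec.is_metazoan else 'false'}"
                     f"\t{rec.phylum}\n")


def read_coverage(path) -> CoverageTable:
    """2-column TSV feature_id -> mean depth; an optional header is skipped."""
    table = CoverageTable()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError("expected 2 fields", path=path, line=lineno)
            fid, depth = fields
            try:
                value = float(depth)
            except ValueError:
                if lineno == 1:  # tolerate a header row
                    continue
                raise ParseError(f"not a number: {depth!r}", path=path,
                                 line=lineno) from None
            if value < 0:
                raise ValidationError(
                    f"{path}:{lineno}: negative coverage for {fid}"
                )
            table[fid] = value
    return table


def write_coverage(table: CoverageTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("feature_id\tmean_depth\n")
        for fid in sorted(table):
            fh.write(f"{fid}\t{_fmt(table[fid])}\n")


def read_loci(path, fmt: str = "auto") -> list[GeneLocus]:
    """Read gene placements from BED6 (native) or a GFF3 subset.

    GFF3 'gene' features are converted from 1-based closed to 0-based
    half-open; the gene id is taken from the ID= attribute.
    """
    if fmt == "auto":
        fmt = "gff3" if str(path).endswith((".gff", ".gff3")) else "bed"
    loci: list[GeneLocus] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if fmt == "bed":
                    if len(fields) < 4:
                        raise ParseError("BED needs >= 4 fields", path=path,
                                         line=lineno)
                    strand = fields[5] if len(fields) >= 6 else "."
                    loci.append(GeneLocus(
                        gene_id=fields[3], scaffold_id=fields[0],
                        start=int(fields[1]), end=int(fields[2]),
                        strand=strand,
                    ))
                elif fmt == "gff3":
                    if len(fields) != 9:
                        raise ParseError("GFF3 needs 9 fields", path=path,
                                         line=lineno)
                    attrs = dict(
                        kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
                    )
                    loci.append(GeneLocus(
                        gene_id=attrs.get("ID", f"feature{lineno}"),
                        scaffold_id=fields[0],
                        start=int(fields[3]) - 1, end=int(fields[4]),
                        strand=fields[6],
                    ))
                else:
                    raise ValueError(f"unknown loci format {fmt!r}")
            except (ValueError, ValidationError) as exc:
                raise ParseError(str(exc), path=path, line=lineno) from exc
    return loci


def write_loci(loci: Iterable[GeneLocus], path) -> None:
    """Write BED6, sorted by (scaffold, start, gene_id)."""
    rows = sorted(loci, key=lambda l: (l.scaffold_id, l.start, l.gene_id))
    with open(path, "w", encoding="utf-8") as fh:
        for l in rows:
            fh.write(f"{l.scaffold_id}\t{l.start}\t{l.end}\t{l.gene_id}"
                     f"\t.\t{l.strand}\n")


FLAGS_COLUMNS = ("protein_id", "secretion", "tm", "nglyc")


def read_flags(path) -> dict[str, tuple[bool, bool, bool]]:
    """External predictor flags: protein_id, secretion, tm, nglyc (booleans)."""
    flags: dict[str, tuple[bool, bool, bool]] = {}
    with open(path, encoding="utf-8") as fh:
        header = tuple(fh.readline().rstrip("\n").split("\t"))
        if header != FLAGS_COLUMNS:
            raise SchemaError(
                f"flags table requires columns {FLAGS_COLUMNS}, got {header}"
            )
        for lineno, raw in enumerate(fh, 2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError("expected 4 fields", path=path, line=lineno)
            pid = fields[0]
            if pid in flags:
                raise ConsistencyError(f"protein {pid} flagged twice")
            flags[pid] = tuple(_parse_bool(f, path, lineno) for f in fields[1:])
    return flags


def write_flags(flags: Mapping[str, tuple[bool, bool, bool]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(FLAGS_COLUMNS) + "\n")
        for pid in sorted(flags):
            s, t, n = flags[pid]
            fh.write(f"{pid}\t{_bool(s)}\t{_bool(t)}\t{_bool(n)}\n")


def _bool(b: bool) -> str:
    return "true" if b else "false"


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    """id -> sequence, in file order."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path, width: int = 60) -> None:
    records = [SeqRecord(Seq(seq), id=sid, description="")
               for sid, seq in sequences.items()]
    with open(path, "w", encoding="utf-8") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# generic report writers


def write_tsv(rows: Iterable[Mapping], path, columns: list[str],
              header_comment: str | None = None) -> None:
    """Tab-separated report with a fixed column order.

    Rows are emitted in the given order; callers sort by id beforehand.
    """
    with open(path, "w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(_cell(row[c]) for c in columns) + "\n")


def _cell(v) -> str:
    if isinstance(v, bool):
        return _bool(v)
    if isinstance(v, float):
        return _fmt(v)
    return str(v)


def write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
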