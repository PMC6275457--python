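"""C-type lectin domain (CTLD) motif tabulation.

Lectin-active CTLDs typically carry the tripeptide "WND" in the
carbohydrate-recognition site, together with "EPN" (mannose specificity) or
"QPD" (galactose specificity).  This module scans protein sequences for
those literal motifs — optionally restricted to annotated domain
intervals — merges the result with externally produced secretion /
transmembrane / N-glycosylation flags, and renders per-cluster summary
tables in the conventional "count (percent)" style.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

from .errors import ConsistencyError, ValidationError
from .io import OrthoGroupSet

MOTIFS = ("EPN", "WND", "QPD")

_AMINO = frozenset("ACDEFGHIKLMNPQRSTVWYX*")


@dataclass
class MotifProfile:
    protein_id: str
    has_EPN: bool = False
    has_WND: bool = False
    has_QPD: bool = False
    positions: list[tuple[str, int]] = field(default_factory=list)
    secretion_flag: bool = False
    tm_flag: bool = False
    nglyc_flag: bool = False

    def has(self, motif: str) -> bool:
        return getattr(self, f"has_{motif}")


def scan_motifs(
    protein_id: str,
    sequence: str,
    domain_intervals: Sequence[tuple[int, int]] | None = None,
) -> MotifProfile:
    """Exact, case-insensitive substring search for EPN/WND/QPD.

    When *domain_intervals* (0-based half-open) are given, only matches
    lying entirely inside an interval are recorded.  All (possibly
    overlapping) occurrences are kept, with 0-based offsets.
    """
    seq = sequence.upper()
    bad = [i for i, aa in enumerate(seq) if aa not in _AMINO]
    if bad:
        raise ValidationError(
            f"{protein_id}: invalid residue at position(s) "
            + ", ".join(str(i) for i in bad[:5])
        )
    if domain_intervals is not None:
        for start, end in domain_intervals:
            if not (0 <= start < end <= len(seq)):
                raise ValidationError(
                    f"{protein_id}: interval ({start},{end}) outside sequence"
                )
    profile = MotifProfile(protein_id=protein_id)
    for motif in MOTIFS:
        start = 0
        while True:
            pos = seq.find(motif, start)
            if pos == -1:
                break
            inside = domain_intervals is None or any(
                s <= pos and pos + len(motif) <= e
                for s, e in domain_intervals
            )
            if inside:
                profile.positions.append((motif, pos))
                setattr(profile, f"has_{motif}", True)
            start = pos + 1
    profile.positions.sort(key=lambda t: (t[1], t[0]))
    return profile


def format_count_pct(count: int, total: int) -> str:
    """Render "count (percent)" with the percent at one decimal, rounded
    half-away-from-zero; a zero count renders as plain "0"."""
    if total <= 0:
        raise ValidationError("total must be positive")
    if not 0 <= count <= total:
        raise ValidationError(f"count {count} outside [0, {total}]")
    if count == 0:
        return "0"
    pct = (Decimal(100 * count) / Decimal(total)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP
    )
    return f"{count} ({pct})"


@dataclass
class ClusterSummary:
    cluster_id: str
    n_genes: int
    counts: dict[str, int]

    def cell(self, key: str) -> str:
        return format_count_pct(self.counts[key], self.n_genes)

    def row(self) -> dict:
        return {
            "cluster_id": self.cluster_id,
            "n_genes": self.n_genes,
            **{key: self.cell(key) for key in SUMMARY_KEYS},
        }


SUMMARY_KEYS = ("secretion", "tm", "nglyc", "EPN", "WND", "QPD")
SUMMARY_COLUMNS = ["cluster_id", "n_genes", *SUMMARY_KEYS]


def cluster_summary(
    profiles: Sequence[MotifProfile],
    clusters: OrthoGroupSet,
) -> list[ClusterSummary]:
    """One summary row per cluster (cluster-id order), plus an
    "unclustered" row when any profiled protein is in no cluster."""
    by_id: dict[str, MotifProfile] = {p.protein_id: p for p in profiles}
    missing = [m for members in clusters.groups.values() for m in members
               if m not in by_id]
    if missing:
        raise ConsistencyError(
            "no profile for cluster member(s): "
            + ", ".join(sorted(missing)[:5])
        )

    def tally(members: Sequence[str], cid: str) -> ClusterSummary:
        counts = {
            "secretion": sum(by_id[m].secretion_flag for m in members),
            "tm": sum(by_id[m].tm_flag for m in members),
            "nglyc": sum(by_id[m].nglyc_flag for m in members),
            "EPN": sum(by_id[m].has_EPN for m in members),
            "WND": sum(by_id[m].has_WND for m in members),
            "QPD": sum(by_id[m].has_QPD for m in members),
        }
        return ClusterSummary(cluster_id=cid, n_genes=len(members),
                              counts=counts)

    summaries = [tally(clusters.members(gid), gid)
                 for gid in sorted(clusters.groups)]
    unclustered = sorted(p.protein_id for p in profiles
                         if clusters.group_of(p.protein_id) is None)
    if unclustered:
        summaries.append(tally(unclustered, "unclustered"))
    return summaries
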