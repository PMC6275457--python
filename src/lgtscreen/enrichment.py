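"""Hypergeometric enrichment of protein domains with BH-FDR correction.

Given a background proteome (N proteins, K carrying a domain) and an
observed subset (n proteins, k carrying it), the upper-tail hypergeometric
probability P(X >= k) tests for over-representation.  P values across
domains are adjusted by the Benjamini-Hochberg step-up procedure and
significance is declared on the adjusted value at alpha (0.05 by default);
fold enrichment is (k/n)/(K/N).  Domain counting is per-protein
presence/absence: a protein carrying two copies of a domain counts once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ConsistencyError, ValidationError


@dataclass(frozen=True)
class EnrichmentInput:
    N: int  # background set size
    K: int  # background proteins carrying the domain
    n: int  # observed set size
    k: int  # observed proteins carrying the domain

    def __post_init__(self):
        if not (0 <= self.K <= self.N and 0 <= self.n <= self.N):
            raise ValidationError(f"invalid design {self}")
        if not 0 <= self.k <= min(self.K, self.n):
            raise ValidationError(f"k out of range in {self}")


@dataclass
class EnrichmentResult:
    domain_id: str
    counts: EnrichmentInput
    p_value: float
    q_value: float = float("nan")
    fold: float = float("nan")
    significant: bool = False


RESULT_COLUMNS = ["domain_id", "k", "n", "K", "N", "fold", "p_value",
                  "q_value", "significant"]


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    EnrichmentInput(N, K, n, k)  # bounds check
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    if any(not 0.0 <= p <= 1.0 for p in p_values):
        raise ValidationError("p values must lie in [0, 1]")
    if len(p_values) == 0:
        return []
    _, q, _, _ = multipletests(list(p_values), method="fdr_bh")
    return [float(x) for x in q]


def _presence(table: Mapping[str, Sequence[str]]) -> dict[str, set[str]]:
    """domain -> set of proteins carrying it (copy number collapsed)."""
    out: dict[str, set[str]] = {}
    for pid, domains in table.items():
        for d in domains:
            out.setdefault(d, set()).add(pid)
    return out


def domain_enrichment(
    observed: Mapping[str, Sequence[str]],
    background: Mapping[str, Sequence[str]],
    alpha: float = 0.05,
    min_unique_peptides: int = 2,
    peptide_support: Mapping[str, int] | None = None,
    threshold_on: str = "q",
) -> list[EnrichmentResult]:
    """Test every domain present in the observed set for enrichment.

    *observed* / *background* map protein_id -> iterable of domain ids.
    When *peptide_support* is given, observed proteins with fewer than
    *min_unique_peptides* unique peptides are excluded before counting.
    ``threshold_on`` is "q" (BH-adjusted, default) or "p" (raw).
    Results are sorted by (q, p, domain_id).
    """
    if threshold_on not in {"q", "p"}:
        raise ValidationError(f"bad threshold_on {threshold_on!r}")
    stray = sorted(set(observed) - set(background))
    if stray:
        raise ConsistencyError(
            "observed protein(s) absent from background: "
            + ", ".join(stray[:5])
        )
    if peptide_support is not None:
        observed = {pid: doms for pid, doms in observed.items()
                    if peptide_support.get(pid, 0) >= min_unique_peptides}

    N = len(background)
    n = len(observed)
    bg = _presence(background)
    ob = _presence(observed)

    results: list[EnrichmentResult] = []
    for domain in sorted(ob):
        k = len(ob[domain])
        K = len(bg.get(domain, set()) | ob[domain])
        counts = EnrichmentInput(N=N, K=K, n=n, k=k)
        p = hypergeom_tail(N, K, n, k)
        fold = (k / n) / (K / N) if n and K else float("nan")
        results.append(EnrichmentResult(domain_id=domain, counts=counts,
                                        p_value=p, fold=fold))
    qs = bh_adjust([r.p_value for r in results])
    for r, q in zip(results, qs):
        r.q_value = q
        r.significant = (q if threshold_on == "q" else r.p_value) < alpha
    results.sort(key=lambda r: (r.q_value, r.p_value, r.domain_id))
    return results


def result_rows(results: Sequence[EnrichmentResult]) -> list[dict]:
    return [
        {
            "domain_id": r.domain_id,
            "k": r.counts.k, "n": r.counts.n,
            "K": r.counts.K, "N": r.counts.N,
            "fold": r.fold, "p_value": r.p_value, "q_value": r.q_value,
            "significant": r.significant,
        }
        for r in results
    ]
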