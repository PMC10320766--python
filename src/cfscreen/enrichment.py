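"""Hypergeometric gene-set enrichment with multiple-testing adjustment.

Three analyses share one engine:

* essentiality enrichment of functional categories / complexes against the
  genome background (N protein-coding genes, K essential genome-wide);
* per-promoter directional enrichment of categories / complexes among the
  regulators whose knockdown increased (or decreased) a reporter, against
  the screened library as background;
* tissue-expression enrichment among regulators with any interaction.

All tests are one-sided upper tails, P(X >= k), computed in log space.
Benjamini-Hochberg adjustment is applied within each analysis family; raw
p-values are always reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from cfscreen._util import percent
from cfscreen.annotations import CofactorRecord, GenomeBackground
from cfscreen.network import BipartiteNetwork

__all__ = [
    "EnrichmentResult",
    "hypergeom_upper_tail",
    "essentiality_enrichment",
    "promoter_enrichment",
    "tissue_enrichment",
    "adjust_pvalues",
    "results_to_frame",
    "write_enrichment_tsv",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """One hypergeometric test: k of n foreground vs K of N background."""

    foreground_label: str
    background_label: str
    direction: str  # increase | decrease | any
    k: int
    K: int
    n: int
    N: int
    p_raw: float
    p_adj: float
    percent_fg: int | None = None  # e.g. percent essential in the group

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.K) and self.n <= self.N and self.K <= self.N):
            raise ValueError(
                f"invalid contingency bounds: k={self.k} K={self.K} n={self.n} N={self.N}"
            )


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    Drawing ``n`` items without replacement from a population of ``N``
    containing ``K`` successes; the tail is accumulated in log space for
    numerical stability (tiny tails at genome-scale N).
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(n, K)):
        raise ValueError(f"invalid parameters: k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    i = np.arange(k, min(n, K) + 1)
    logp = stats.hypergeom.logpmf(i, N, K, n)
    return float(min(1.0, np.exp(logsumexp(logp))))


def adjust_pvalues(p_values: Sequence[float], method: str = "fdr_bh") -> np.ndarray:
    """Multiple-testing adjustment preserving the input order.

    ``fdr_bh`` applies the Benjamini-Hochberg step-up (monotone in the raw
    ordering); ``none`` returns the raw values unchanged (mirroring
    uncorrected reporting).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if method == "none":
        return p.copy()
    if method == "fdr_bh":
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown adjustment method {method!r}")


def _groups_of(records: Sequence[CofactorRecord]) -> dict[tuple[str, str], set[str]]:
    """(kind, label) -> gene ids, over categories and complexes."""
    groups: dict[tuple[str, str], set[str]] = {}
    for r in records:
        for c in r.categories:
            groups.setdefault(("category", c), set()).add(r.gene_id)
        for c in r.complexes:
            groups.setdefault(("complex", c), set()).add(r.gene_id)
    return dict(sorted(groups.items()))


def essentiality_enrichment(
    records: Sequence[CofactorRecord],
    background: GenomeBackground,
    *,
    adjust: str = "fdr_bh",
    include_overall: bool = True,
    deduplicate_overall: bool = True,
) -> list[EnrichmentResult]:
    """Test each category and complex for enrichment of essential genes.

    Background: the genome (``N = background.n_genes`` protein-coding
    genes, ``K = background.n_essential`` essential genome-wide).  Each
    group contributes one test with ``n`` = group size and ``k`` =
    essential members; the group's percent-essential is reported for
    figure-style summaries.  ``include_overall`` adds an ``all_CFs`` row;
    with ``deduplicate_overall`` (default) it counts unique genes, else it
    sums category memberships (genes in two categories counted twice).
    """
    if background.n_genes < len({r.gene_id for r in records}):
        raise ValueError("genome background smaller than the annotated gene set")
    essential_ids = {r.gene_id for r in records if r.essential}
    groups = _groups_of(records)
    rows: list[EnrichmentResult] = []
    for (kind, label), genes in groups.items():
        n, k = len(genes), len(genes & essential_ids)
        p = hypergeom_upper_tail(k, background.n_essential, n, background.n_genes)
        rows.append(
            EnrichmentResult(
                foreground_label=f"{kind}:{label}",
                background_label="genome",
                direction="any",
                k=k,
                K=background.n_essential,
                n=n,
                N=background.n_genes,
                p_raw=p,
                p_adj=p,
                percent_fg=percent(k, n) if n else None,
            )
        )
    if include_overall and records:
        if deduplicate_overall:
            n = len({r.gene_id for r in records})
            k = len(essential_ids)
        else:
            n = sum(max(1, len(r.categories)) for r in records)
            k = sum(max(1, len(r.categories)) for r in records if r.essential)
        p = hypergeom_upper_tail(
            min(k, background.n_essential), background.n_essential, n, background.n_genes
        )
        rows.append(
            EnrichmentResult(
                foreground_label="all_CFs",
                background_label="genome",
                direction="any",
                k=k,
                K=background.n_essential,
                n=n,
                N=background.n_genes,
                p_raw=p,
                p_adj=p,
                percent_fg=percent(k, n),
            )
        )
    adj = adjust_pvalues([r.p_raw for r in rows], adjust)
    return [replace(r, p_adj=float(a)) for r, a in zip(rows, adj)]


def _tested_ids(records: Sequence[CofactorRecord], background: str) -> set[str]:
    if background == "library":
        return {r.gene_id for r in records if r.in_library}
    if background == "all":
        return {r.gene_id for r in records}
    raise ValueError(f"unknown background {background!r}; expected 'library' or 'all'")


def promoter_enrichment(
    net: BipartiteNetwork,
    records: Sequence[CofactorRecord],
    direction: str,
    *,
    background: str = "library",
    adjust: str = "fdr_bh",
) -> list[EnrichmentResult]:
    """Directional group x promoter enrichment grid.

    For each (category-or-complex group, promoter): ``N`` = regulators in
    the sampling frame (the screened library by default), ``K`` = group
    members among them, ``n`` = regulators with a ``direction``-matching
    edge to the promoter, ``k`` = the overlap.  The formulation is
    symmetric in the group and the hit set, so swapping their roles leaves
    ``p_raw`` unchanged.  BH adjustment spans the whole grid (one family
    per direction).
    """
    if direction not in ("increase", "decrease"):
        raise ValueError(f"direction must be 'increase' or 'decrease', got {direction!r}")
    want = 1 if direction == "increase" else -1
    tested = _tested_ids(records, background)
    groups = _groups_of(records)
    hits_by_prom: dict[str, set[str]] = {p: set() for p in net.promoters}
    for r, p, s in net.edges:
        if s == want and r in tested:
            hits_by_prom[p].add(r)
    N = len(tested)
    rows: list[EnrichmentResult] = []
    for (kind, label), genes in groups.items():
        K = len(genes & tested)
        for prom in net.promoters:
            hits = hits_by_prom[prom]
            n, k = len(hits), len(hits & genes)
            p = hypergeom_upper_tail(k, K, n, N)
            rows.append(
                EnrichmentResult(
                    foreground_label=f"{kind}:{label}",
                    background_label=prom,
                    direction=direction,
                    k=k,
                    K=K,
                    n=n,
                    N=N,
                    p_raw=p,
                    p_adj=p,
                )
            )
    adj = adjust_pvalues([r.p_raw for r in rows], adjust)
    return [replace(r, p_adj=float(a)) for r, a in zip(rows, adj)]


def tissue_enrichment(
    net: BipartiteNetwork,
    records: Sequence[CofactorRecord],
    tissue: str,
    *,
    background: str = "library",
) -> EnrichmentResult:
    """Are tissue-expressed regulators over-represented among interactors?

    ``N`` = tested regulators, ``K`` = tissue-expressed among them,
    ``n`` = regulators with at least one final edge, ``k`` =
    tissue-expressed among those.
    """
    known = set().union(*(r.tissues for r in records)) if records else set()
    if tissue not in known:
        raise LookupError(f"unknown tissue label {tissue!r}")
    tested = _tested_ids(records, background)
    expressed = {r.gene_id for r in records if tissue in r.tissues} & tested
    interacting = {r for r, _, _ in net.edges} & tested
    k = len(interacting & expressed)
    p = hypergeom_upper_tail(k, len(expressed), len(interacting), len(tested))
    return EnrichmentResult(
        foreground_label=f"tissue:{tissue}",
        background_label="library" if background == "library" else "all_records",
        direction="any",
        k=k,
        K=len(expressed),
        n=len(interacting),
        N=len(tested),
        p_raw=p,
        p_adj=p,
    )


def results_to_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "foreground": r.foreground_label,
                "background": r.background_label,
                "direction": r.direction,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
                "percent_fg": r.percent_fg,
            }
            for r in results
        ]
    )


def write_enrichment_tsv(results: Iterable[EnrichmentResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False)
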