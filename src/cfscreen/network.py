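"""Signed bipartite network assembly and degree/sign statistics.

Sign convention throughout: an edge of sign -1 means knockdown of the
regulator *decreased* reporter fluorescence (the regulator is a candidate
activator of the promoter); +1 means fluorescence increased (candidate
repressor).  A regulator with edges of both signs is bifunctional.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats

from cfscreen._util import percent
from cfscreen.hitcalling import InteractionCall

__all__ = [
    "BipartiteNetwork",
    "build_network",
    "classify_regulators",
    "summary_fractions",
    "NetworkSummary",
    "degree_by_group_test",
    "MannWhitneyResult",
    "cross_class_fractions",
    "export_network",
    "read_network_tsv",
]

#: Exact-enumeration threshold for the rank-sum test: at or below this
#: combined sample size the permutation null of U is enumerated fully.
EXACT_ENUMERATION_MAX_N = 12


@dataclass(frozen=True)
class BipartiteNetwork:
    """Signed regulator -> promoter graph with derived degree maps."""

    promoters: tuple[str, ...]
    regulators: tuple[str, ...]
    edges: frozenset[tuple[str, str, int]]
    k_out: dict[str, int] = field(default_factory=dict)
    k_in: dict[str, int] = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edges_of(self, regulator: str) -> list[tuple[str, str, int]]:
        return [e for e in self.edges if e[0] == regulator]


def build_network(
    calls: Sequence[InteractionCall],
    promoters: Sequence[str] | None = None,
) -> BipartiteNetwork:
    """Assemble the network from final interaction calls.

    Non-final calls are ignored; regulators without a final call are
    excluded.  ``promoters`` fixes the promoter panel (so reporters with
    zero in-degree are kept in ``k_in``); by default the panel is the set
    of reporters appearing in final calls.  Duplicate (regulator, reporter)
    pairs with conflicting sign raise ``ValueError``.
    """
    final = [c for c in calls if c.final]
    seen: dict[tuple[str, str], int] = {}
    for c in final:
        key = (c.regulator_id, c.reporter_id)
        if key in seen and seen[key] != c.sign:
            raise ValueError(f"conflicting duplicate edge signs for pair {key}")
        seen[key] = c.sign
    edges = frozenset((r, p, s) for (r, p), s in seen.items())
    regs = tuple(sorted({r for r, _, _ in edges}))
    if promoters is None:
        proms = tuple(sorted({p for _, p, _ in edges}))
    else:
        proms = tuple(promoters)
        missing = {p for _, p, _ in edges} - set(proms)
        if missing:
            raise ValueError(f"final calls mention unlisted promoter(s): {sorted(missing)}")
    k_out = {r: 0 for r in regs}
    k_in = {p: 0 for p in proms}
    for r, p, _ in edges:
        k_out[r] += 1
        k_in[p] += 1
    return BipartiteNetwork(
        promoters=proms, regulators=regs, edges=edges, k_out=k_out, k_in=k_in
    )


def classify_regulators(net: BipartiteNetwork) -> dict[str, str]:
    """Classify each regulator as activator, repressor or bifunctional.

    All edges sign -1 (knockdown decreases fluorescence) -> ``activator``;
    all +1 -> ``repressor``; both signs -> ``bifunctional``.  The classes
    partition the regulators with at least one edge.
    """
    signs: dict[str, set[int]] = {}
    for r, _, s in net.edges:
        signs.setdefault(r, set()).add(s)
    out = {}
    for r, ss in signs.items():
        if ss == {-1}:
            out[r] = "activator"
        elif ss == {1}:
            out[r] = "repressor"
        else:
            out[r] = "bifunctional"
    return out


@dataclass(frozen=True)
class NetworkSummary:
    """Headline network fractions with their denominators."""

    n_edges: int
    n_regulators: int
    n_promoters: int
    n_multi_target: int
    n_bifunctional_multi: int
    n_decreasing_edges: int
    pct_multi_target: int | None
    pct_bifunctional_among_multi: int | None
    pct_decreasing_edges: int | None


def summary_fractions(net: BipartiteNetwork) -> NetworkSummary:
    """Fractions of multi-target, bifunctional, and decreasing interactions.

    Percentages are integer, rounded half-up, reported with their
    denominators; an empty network reports every percentage as ``None``
    (undefined), never as zero.
    """
    classes = classify_regulators(net)
    multi = [r for r in net.regulators if net.k_out.get(r, 0) >= 2]
    bif_multi = [r for r in multi if classes[r] == "bifunctional"]
    n_dec = sum(1 for _, _, s in net.edges if s == -1)
    n_reg, n_edge, n_multi = len(net.regulators), net.n_edges, len(multi)
    return NetworkSummary(
        n_edges=n_edge,
        n_regulators=n_reg,
        n_promoters=len(net.promoters),
        n_multi_target=n_multi,
        n_bifunctional_multi=len(bif_multi),
        n_decreasing_edges=n_dec,
        pct_multi_target=percent(n_multi, n_reg) if n_reg else None,
        pct_bifunctional_among_multi=percent(len(bif_multi), n_multi) if n_multi else None,
        pct_decreasing_edges=percent(n_dec, n_edge) if n_edge else None,
    )


@dataclass(frozen=True)
class MannWhitneyResult:
    statistic: float  # U statistic of group A
    pvalue: float
    method: str  # "exact" or "asymptotic"


def degree_by_group_test(
    group_a: Sequence[float], group_b: Sequence[float]
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney rank-sum comparison of two degree samples.

    For combined sample size up to ``EXACT_ENUMERATION_MAX_N`` the p-value
    is computed by full enumeration of all rank assignments (midranks for
    ties; two-sided p is twice the smaller tail of the permutation
    distribution of U, capped at 1).  Larger samples use the normal
    approximation with continuity and tie correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n = a.size + b.size
    if n <= EXACT_ENUMERATION_MAX_N:
        values = np.concatenate([a, b])
        ranks = stats.rankdata(values)
        offset = a.size * (a.size + 1) / 2.0
        u_obs = ranks[: a.size].sum() - offset
        combos = np.array(
            list(itertools.combinations(range(n), a.size)), dtype=int
        )
        u_all = ranks[combos].sum(axis=1) - offset
        # tiny float slack so midrank sums compare reliably
        eps = 1e-9
        p_ge = np.mean(u_all >= u_obs - eps)
        p_le = np.mean(u_all <= u_obs + eps)
        p = min(1.0, 2.0 * min(p_ge, p_le))
        return MannWhitneyResult(statistic=float(u_obs), pvalue=float(p), method="exact")
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", use_continuity=True, method="asymptotic"
    )
    return MannWhitneyResult(
        statistic=float(res.statistic), pvalue=float(res.pvalue), method="asymptotic"
    )


def cross_class_fractions(
    nets: Mapping[str, BipartiteNetwork],
    tested_counts: Mapping[str, int],
) -> pd.DataFrame:
    """Per-promoter percentage of tested genes interacting, per gene class.

    ``nets`` maps a gene class (e.g. cofactors, metabolic genes, TFs) to
    its network over a shared promoter panel; ``tested_counts`` gives the
    number of genes of that class that were screened (the denominator).
    Returns a promoters x classes table of ``100 * k_in / tested``.
    """
    classes = list(nets)
    missing = [c for c in classes if c not in tested_counts]
    if missing:
        raise ValueError(f"missing tested_counts for class(es): {missing}")
    panel: list[str] = []
    for c, net in nets.items():
        for p in net.promoters:
            if p not in panel:
                panel.append(p)
    for c, net in nets.items():
        absent = set(panel) - set(net.promoters)
        if absent:
            raise ValueError(
                f"class {c!r} network lacks promoter(s) {sorted(absent)} of the shared panel"
            )
    data = {
        c: [100.0 * nets[c].k_in.get(p, 0) / tested_counts[c] for p in panel]
        for c in classes
    }
    return pd.DataFrame(data, index=pd.Index(panel, name="promoter"))


_SIF_TYPE = {-1: "activates", 1: "represses"}
_SIGN_OF_SIF = {v: k for k, v in _SIF_TYPE.items()}


def export_network(net: BipartiteNetwork, path: str | Path, fmt: str = "tsv") -> None:
    """Write the network as a TSV edge list, SIF, or GraphML file.

    SIF maps sign -1 to ``activates`` and +1 to ``represses`` (knockdown
    phenotype read as the regulator's native role).  GraphML stores the
    sign as an edge attribute and the bipartite part (``regulator`` /
    ``promoter``) as a node attribute.  The TSV form round-trips
    losslessly through :func:`read_network_tsv`.
    """
    path = Path(path)
    ordered = sorted(net.edges)
    if fmt == "tsv":
        pd.DataFrame(ordered, columns=["regulator", "reporter", "sign"]).to_csv(
            path, sep="\t", index=False
        )
    elif fmt == "sif":
        lines = [f"{r}\t{_SIF_TYPE[s]}\t{p}" for r, p, s in ordered]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "graphml":
        g = nx.DiGraph()
        for r in net.regulators:
            g.add_node(r, part="regulator")
        for p in net.promoters:
            g.add_node(p, part="promoter")
        for r, p, s in ordered:
            g.add_edge(r, p, sign=int(s))
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown export format {fmt!r}; expected tsv, sif or graphml")


def read_network_tsv(path: str | Path, promoters: Sequence[str] | None = None) -> BipartiteNetwork:
    """Rebuild a network from a TSV edge list written by :func:`export_network`."""
    df = pd.read_csv(path, sep="\t")
    edges = frozenset(
        (row.regulator, row.reporter, int(row.sign))
        for row in df.itertuples(index=False)
    )
    regs = tuple(sorted({r for r, _, _ in edges}))
    proms = tuple(promoters) if promoters is not None else tuple(
        sorted({p for _, p, _ in edges})
    )
    k_out = {r: 0 for r in regs}
    k_in = {p: 0 for p in proms}
    for r, p, _ in edges:
        k_out[r] += 1
        k_in[p] += 1
    return BipartiteNetwork(
        promoters=proms, regulators=regs, edges=edges, k_out=k_out, k_in=k_in
    )
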