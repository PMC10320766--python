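"""Synthetic screen generator: planted networks and noisy replicate tables.

The generator emulates the structure of a gene-centered visual RNAi screen:
a ground-truth signed bipartite network between ~335 regulators and 19
promoter reporters at ~3.3% interaction density, with ~61% of interactions
decreasing reporter fluorescence on knockdown, optional hub regulators
(a cbp-1-like regulator touching 14/19 promoters) and optional complex
blocks whose members share edges.  Observations are then simulated through
the three-tier replicate cascade (3 primary, 2 retest, 2 imaging
replicates) with per-replicate detection failures and false-positive calls,
so that every downstream stage can be tested without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CALL_NONE",
    "CALL_INCREASE",
    "CALL_DECREASE",
    "TIERS",
    "GroundTruthModel",
    "NoiseModel",
    "generate_ground_truth",
    "simulate_replicates",
    "write_observations",
    "read_observations",
    "write_ground_truth",
    "read_ground_truth",
    "generate_cofactor_records",
    "CATEGORY_VOCABULARY",
]

CALL_NONE = "none"
CALL_INCREASE = "increase"
CALL_DECREASE = "decrease"
TIERS = ("primary", "retest", "imaging")

#: Replicates per tier: triplicate primary screen, duplicate retest,
#: duplicate imaging confirmation.
TIER_REPLICATES = {"primary": 3, "retest": 2, "imaging": 2}

_CALL_OF_SIGN = {0: CALL_NONE, 1: CALL_INCREASE, -1: CALL_DECREASE}


@dataclass(frozen=True)
class GroundTruthModel:
    """A planted signed bipartite regulator -> promoter network.

    ``edges`` maps (regulator, promoter) to a sign: +1 means knockdown
    increases reporter fluorescence, -1 means it decreases it.
    """

    regulators: tuple[str, ...]
    promoters: tuple[str, ...]
    edges: dict[tuple[str, str], int]
    seed: int

    def __post_init__(self) -> None:
        regs, proms = set(self.regulators), set(self.promoters)
        for (r, p), s in self.edges.items():
            if r not in regs or p not in proms:
                raise ValueError(f"edge endpoint not in node lists: {(r, p)}")
            if s not in (1, -1):
                raise ValueError(f"edge sign must be +1 or -1, got {s}")

    @property
    def density(self) -> float:
        return len(self.edges) / (len(self.regulators) * len(self.promoters))

    def sign_matrix(self) -> np.ndarray:
        """Dense (n_regulators, n_promoters) matrix of signs, 0 = no edge."""
        ridx = {r: i for i, r in enumerate(self.regulators)}
        pidx = {p: j for j, p in enumerate(self.promoters)}
        m = np.zeros((len(self.regulators), len(self.promoters)), dtype=np.int8)
        for (r, p), s in self.edges.items():
            m[ridx[r], pidx[p]] = s
        return m


@dataclass(frozen=True)
class NoiseModel:
    """Per-replicate observation noise of the visual screen.

    ``p_primary``, ``p_retest``, ``p_photo`` are the probabilities that a
    true interaction is seen in one replicate of the respective tier;
    ``q_fp`` is the probability that a non-interaction is called in one
    replicate; ``sign_flip`` the probability that a detected true edge is
    called with the wrong direction.
    """

    p_primary: float = 0.9
    p_retest: float = 0.9
    p_photo: float = 0.9
    q_fp: float = 0.005
    sign_flip: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_primary", "p_retest", "p_photo", "q_fp", "sign_flip"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def _promoter_names(promoters: int | Sequence[str]) -> tuple[str, ...]:
    if isinstance(promoters, int):
        return tuple(f"prom-{j + 1:02d}" for j in range(promoters))
    return tuple(promoters)


def generate_ground_truth(
    n_regulators: int = 335,
    promoters: int | Sequence[str] = 19,
    density: float = 0.033,
    decrease_fraction: float = 0.61,
    hub_spec: tuple[int, int] | None = None,
    complex_blocks: tuple[Sequence[Sequence[int]], float] | None = None,
    seed: int = 0,
) -> GroundTruthModel:
    """Sample a planted signed bipartite network.

    Edges are Bernoulli(``density``) independently per regulator-promoter
    pair; signs are independent with P(decrease) = ``decrease_fraction``.
    Two structured deviations are available:

    * ``hub_spec = (n_hubs, k_out)`` forces the first ``n_hubs`` regulators
      to exactly ``k_out`` edges (promoters drawn without replacement),
      replacing their Bernoulli rows — this guarantees a cbp-1-like hub.
    * ``complex_blocks = (blocks, p_share)`` where ``blocks`` is a sequence
      of regulator-index groups: each block draws one Bernoulli(``density``)
      signed profile and every member inherits each block edge with
      probability ``p_share`` (members' marginal density is then
      ``density * p_share``), producing within-complex profile correlation.
    """
    if not 0.0 <= density <= 1.0:
        raise ValueError(f"density must be in [0, 1], got {density}")
    if not 0.0 <= decrease_fraction <= 1.0:
        raise ValueError(
            f"decrease_fraction must be in [0, 1], got {decrease_fraction}"
        )
    proms = _promoter_names(promoters)
    regs = tuple(f"cf-{i + 1:04d}" for i in range(n_regulators))
    n_p = len(proms)
    rng = np.random.default_rng(seed)

    present = rng.random((n_regulators, n_p)) < density
    signs = np.where(rng.random((n_regulators, n_p)) < decrease_fraction, -1, 1)

    if complex_blocks is not None:
        blocks, p_share = complex_blocks
        if not 0.0 <= p_share <= 1.0:
            raise ValueError(f"p_share must be in [0, 1], got {p_share}")
        for block in blocks:
            idx = np.asarray(block, dtype=int)
            block_present = rng.random(n_p) < density
            block_sign = np.where(rng.random(n_p) < decrease_fraction, -1, 1)
            inherit = rng.random((len(idx), n_p)) < p_share
            present[idx, :] = block_present[None, :] & inherit
            signs[idx, :] = np.broadcast_to(block_sign, (len(idx), n_p))

    if hub_spec is not None:
        n_hubs, k_out = hub_spec
        if k_out > n_p:
            raise ValueError(
                f"hub out-degree {k_out} exceeds number of promoters {n_p}"
            )
        if n_hubs > n_regulators:
            raise ValueError("more hubs requested than regulators")
        for i in range(n_hubs):
            present[i, :] = False
            chosen = rng.choice(n_p, size=k_out, replace=False)
            present[i, chosen] = True
            signs[i, chosen] = np.where(
                rng.random(k_out) < decrease_fraction, -1, 1
            )

    edges = {
        (regs[i], proms[j]): int(signs[i, j])
        for i, j in zip(*np.nonzero(present))
    }
    return GroundTruthModel(regulators=regs, promoters=proms, edges=edges, seed=seed)


def _tier_calls(
    sign: np.ndarray,
    n_reps: int,
    p_detect: float,
    q_fp: float,
    sign_flip: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate signed calls for one tier.

    ``sign`` is the (rows, cols) truth matrix (0 = non-edge).  Returns an
    int8 array of shape (rows, cols, n_reps) in {-1, 0, +1}.
    """
    rows, cols = sign.shape
    u = rng.random((rows, cols, n_reps))
    is_edge = (sign != 0)[:, :, None]
    detected = is_edge & (u < p_detect)
    false_pos = ~is_edge & (u < q_fp)
    flip = rng.random((rows, cols, n_reps)) < sign_flip
    fp_sign = np.where(rng.random((rows, cols, n_reps)) < 0.5, -1, 1).astype(np.int8)
    out = np.zeros((rows, cols, n_reps), dtype=np.int8)
    edge_sign = np.broadcast_to(sign[:, :, None], out.shape)
    out[detected] = (edge_sign * np.where(flip, -1, 1))[detected]
    out[false_pos] = fp_sign[false_pos]
    return out


def simulate_replicates(truth: GroundTruthModel, noise: NoiseModel) -> pd.DataFrame:
    """Simulate the three-tier replicate cascade over a planted network.

    Returns a long-format observation table with columns ``regulator,
    reporter, tier, replicate, call``:

    * exactly 3 primary observations for every regulator-promoter pair
      (including explicit ``none`` calls);
    * 2 retest observations per pair, across *all* promoters, only for
      regulators that trigger candidacy (some pair with >= 2/3 non-none
      primary calls);
    * 2 imaging observations only for pairs passing the combined rule
      (primary positives + retest positives >= 3).

    Identical ``truth``/``noise`` (including seeds) give a byte-identical
    table; per-tier random substreams are derived from ``noise.seed``.
    """
    sign = truth.sign_matrix()
    n_r, n_p = sign.shape
    ss = np.random.SeedSequence(noise.seed)
    rng_primary, rng_retest, rng_imaging = (
        np.random.default_rng(c) for c in ss.spawn(3)
    )

    primary = _tier_calls(sign, 3, noise.p_primary, noise.q_fp, noise.sign_flip, rng_primary)
    prim_pos = (primary != 0).sum(axis=2)
    candidate_regs = (prim_pos >= 2).any(axis=1)

    cand_idx = np.nonzero(candidate_regs)[0]
    retest = _tier_calls(
        sign[cand_idx, :], 2, noise.p_retest, noise.q_fp, noise.sign_flip, rng_retest
    )
    retest_pos = np.zeros((n_r, n_p), dtype=int)
    retest_pos[cand_idx, :] = (retest != 0).sum(axis=2)

    combined = np.zeros((n_r, n_p), dtype=bool)
    combined[cand_idx, :] = (prim_pos[cand_idx, :] + retest_pos[cand_idx, :]) >= 3

    comb_r, comb_p = np.nonzero(combined)
    pair_sign = sign[comb_r, comb_p][:, None]  # (n_pairs, 1)
    imaging = _tier_calls(
        pair_sign, 2, noise.p_photo, noise.q_fp, noise.sign_flip, rng_imaging
    )  # (n_pairs, 1, 2)

    regs = np.asarray(truth.regulators)
    proms = np.asarray(truth.promoters)
    frames = []

    ri, pi, ki = np.meshgrid(np.arange(n_r), np.arange(n_p), np.arange(3), indexing="ij")
    frames.append(
        pd.DataFrame(
            {
                "regulator": regs[ri.ravel()],
                "reporter": proms[pi.ravel()],
                "tier": "primary",
                "replicate": ki.ravel() + 1,
                "call": primary.ravel(),
            }
        )
    )
    if len(cand_idx):
        ri, pi, ki = np.meshgrid(
            cand_idx, np.arange(n_p), np.arange(2), indexing="ij"
        )
        frames.append(
            pd.DataFrame(
                {
                    "regulator": regs[ri.ravel()],
                    "reporter": proms[pi.ravel()],
                    "tier": "retest",
                    "replicate": ki.ravel() + 1,
                    "call": retest.ravel(),
                }
            )
        )
    if len(comb_r):
        frames.append(
            pd.DataFrame(
                {
                    "regulator": np.repeat(regs[comb_r], 2),
                    "reporter": np.repeat(proms[comb_p], 2),
                    "tier": "imaging",
                    "replicate": np.tile([1, 2], len(comb_r)),
                    "call": imaging[:, 0, :].ravel(),
                }
            )
        )
    obs = pd.concat(frames, ignore_index=True)
    obs["call"] = obs["call"].map(_CALL_OF_SIGN)
    obs["tier"] = pd.Categorical(obs["tier"], categories=list(TIERS), ordered=True)
    obs = obs.sort_values(
        ["tier", "regulator", "reporter", "replicate"], ignore_index=True
    )
    obs["tier"] = obs["tier"].astype(str)
    return obs


def write_observations(obs: pd.DataFrame, path: str | Path) -> None:
    obs.to_csv(path, sep="\t", index=False)


def read_observations(path: str | Path) -> pd.DataFrame:
    obs = pd.read_csv(path, sep="\t", dtype={"replicate": int})
    expected = {"regulator", "reporter", "tier", "replicate", "call"}
    missing = expected - set(obs.columns)
    if missing:
        raise ValueError(f"observation table missing column(s): {sorted(missing)}")
    return obs


def write_ground_truth(truth: GroundTruthModel, path: str | Path) -> None:
    rows = [
        {"regulator": r, "reporter": p, "sign": s}
        for (r, p), s in sorted(truth.edges.items())
    ]
    pd.DataFrame(rows, columns=["regulator", "reporter", "sign"]).to_csv(
        path, sep="\t", index=False
    )


def read_ground_truth(
    path: str | Path,
    regulators: Sequence[str] | None = None,
    promoters: Sequence[str] | None = None,
    seed: int = 0,
) -> GroundTruthModel:
    df = pd.read_csv(path, sep="\t")
    edges = {
        (row.regulator, row.reporter): int(row.sign)
        for row in df.itertuples(index=False)
    }
    regs = tuple(regulators) if regulators is not None else tuple(
        sorted({r for r, _ in edges})
    )
    proms = tuple(promoters) if promoters is not None else tuple(
        sorted({p for _, p in edges})
    )
    return GroundTruthModel(regulators=regs, promoters=proms, edges=edges, seed=seed)


#: Functional-category vocabulary used by the synthetic annotation
#: generator (chromatin-writer/eraser/reader classes plus general
#: cofactor machinery).
CATEGORY_VOCABULARY = (
    "methyltransferase",
    "demethylase",
    "histone acetyltransferase",
    "histone deacetylase",
    "histone ubiquitinase",
    "histone phosphatase",
    "histone kinase",
    "remodeler",
    "Mediator component",
    "RNA Pol II-associated",
    "TBP-associated factor",
    "DNA methylation",
    "bromodomain",
    "chromodomain",
    "plant homeodomain",
    "Tudor domain",
)

_TISSUES = (
    "intestine",
    "neuron",
    "muscle",
    "hypodermis",
    "pharynx",
    "germline",
    "glia",
)


def generate_cofactor_records(
    n_records: int = 366,
    clone_counts: tuple[int, int, int] | None = None,
    essential_fraction: float = 0.45,
    intestine_fraction: float = 0.8,
    multi_category_fraction: float = 0.1,
    n_complexes: int = 10,
    complex_fraction: float = 0.25,
    shuffle_sources: bool = True,
    seed: int = 0,
):
    """Generate a synthetic cofactor annotation table.

    Mirrors the shape of a curated cofactor compendium: 366 genes of which
    335 are covered by RNAi clones (186 ORFeome + 95 Ahringer + 54 de
    novo), ~45% carrying an essential phenotype, most expressed in the
    intestine, ~10% annotated in two functional categories, and a quarter
    assigned to one of ``n_complexes`` synthetic complexes.  With
    ``shuffle_sources=False`` the in-library genes occupy the first record
    ids (``cf-0001`` ...), matching the regulator naming of
    :func:`generate_ground_truth` so that simulated screens and annotation
    tables line up.
    """
    from cfscreen.annotations import CofactorRecord, ESSENTIAL_PHENOTYPES

    if clone_counts is None:
        if n_records >= 366:
            clone_counts = (186, 95, 54)
        else:  # keep the ~56/28/16 source mix at reduced scale
            n_lib = max(1, round(n_records * 335 / 366))
            n_orf = round(n_lib * 186 / 335)
            n_ahr = round(n_lib * 95 / 335)
            clone_counts = (n_orf, n_ahr, n_lib - n_orf - n_ahr)
    n_orf, n_ahr, n_new = clone_counts
    n_lib = n_orf + n_ahr + n_new
    if n_lib > n_records:
        raise ValueError("library clone counts exceed the number of records")
    rng = np.random.default_rng(seed)
    sources = (
        ["orfeome"] * n_orf
        + ["ahringer"] * n_ahr
        + ["de_novo"] * n_new
        + ["none"] * (n_records - n_lib)
    )
    if shuffle_sources:
        rng.shuffle(sources)
    else:
        rng.shuffle(sources)  # keep stream alignment; then pin library first
        sources = sorted(sources, key=lambda s: s == "none")
    essential_labels = sorted(ESSENTIAL_PHENOTYPES)
    other_phenotypes = ("slow growth", "dumpy", "uncoordinated", "clear")
    records = []
    for i in range(n_records):
        cats = {CATEGORY_VOCABULARY[rng.integers(len(CATEGORY_VOCABULARY))]}
        if rng.random() < multi_category_fraction:
            cats.add(CATEGORY_VOCABULARY[rng.integers(len(CATEGORY_VOCABULARY))])
        phenos: set[str] = set()
        if rng.random() < essential_fraction:
            phenos.add(essential_labels[rng.integers(len(essential_labels))])
        if rng.random() < 0.3:
            phenos.add(other_phenotypes[rng.integers(len(other_phenotypes))])
        tissues = {t for t in _TISSUES[1:] if rng.random() < 0.4}
        if rng.random() < intestine_fraction:
            tissues.add("intestine")
        complexes: set[str] = set()
        if rng.random() < complex_fraction:
            complexes.add(f"complex-{rng.integers(n_complexes) + 1:02d}")
        records.append(
            CofactorRecord(
                gene_id=f"cf-{i + 1:04d}",
                name=f"cf-{i + 1:04d}",
                categories=frozenset(cats),
                complexes=frozenset(complexes),
                phenotypes=frozenset(phenos),
                tissues=frozenset(tissues),
                clone_source=sources[i],
            )
        )
    from cfscreen.annotations import flag_essential

    return flag_essential(records)
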