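"""Three-tier replicate-cascade hit calling and its operating characteristics.

The screen's decision cascade:

1. *Primary* — every regulator is screened in triplicate against every
   reporter.  A regulator becomes a retest **candidate** if any of its
   pairs shows a fluorescence change (either direction) in at least 2 of
   the 3 primary replicates.
2. *Retest* — candidate regulators are retested in duplicate against all
   reporters.  A pair is a **combined hit** if primary positives plus
   retest positives reach 3 of the 5 combined replicates (a 1/3 primary
   pair can still pass with 2/2 retests).
3. *Imaging* — combined hits are photographed twice; a pair is a **final
   interaction** if at least 1 of the 2 imaged replicates confirms it.

Direction is resolved only at the end: the edge sign is the majority sign
over all non-``none`` calls across tiers, with ties broken by the imaging
majority; a residual tie flags the call ambiguous and drops it from the
final network.

``cascade_sensitivity`` / ``cascade_specificity`` give the closed-form
probability that a true (resp. absent) interaction survives the whole
cascade, conditional on candidacy being triggered through the pair itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "DataError",
    "ConsistencyError",
    "AmbiguousSignError",
    "ReplicateObservation",
    "InteractionCall",
    "primary_candidates",
    "combined_hits",
    "confirmed_interactions",
    "sign_of_pair",
    "cascade_sensitivity",
    "cascade_specificity",
    "observations_to_frame",
    "calls_to_frame",
    "write_calls",
    "read_calls",
]

_VALID_CALLS = ("none", "increase", "decrease")
_SIGN_OF_CALL = {"increase": 1, "decrease": -1, "none": 0, 1: 1, -1: -1, 0: 0}


class DataError(ValueError):
    """Malformed observation table (e.g. >3 primary replicates for a pair)."""


class ConsistencyError(ValueError):
    """Tier gating violated (observations in a tier the pair never reached)."""


class AmbiguousSignError(ValueError):
    """Equal numbers of increase and decrease calls, unresolvable by imaging."""


@dataclass(frozen=True)
class ReplicateObservation:
    """One visual call for one regulator x reporter in one tier/replicate."""

    regulator_id: str
    reporter_id: str
    tier: str
    replicate_index: int
    call: str

    def __post_init__(self) -> None:
        if self.tier not in ("primary", "retest", "imaging"):
            raise ValueError(f"unknown tier {self.tier!r}")
        max_rep = 3 if self.tier == "primary" else 2
        if not 1 <= self.replicate_index <= max_rep:
            raise ValueError(
                f"replicate_index {self.replicate_index} out of range for "
                f"tier {self.tier!r}"
            )
        if self.call not in _VALID_CALLS:
            raise ValueError(f"unknown call {self.call!r}")


@dataclass(frozen=True)
class InteractionCall:
    """A candidate signed edge with its per-tier evidence counts."""

    regulator_id: str
    reporter_id: str
    sign: int
    n_primary_pos: int
    n_retest_pos: int
    n_photo_pos: int
    final: bool
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.final:
            if self.n_primary_pos + self.n_retest_pos < 3:
                raise ValueError("final call below the 3/5 combined threshold")
            if self.n_photo_pos < 1:
                raise ValueError("final call lacks imaging confirmation")
            if self.n_primary_pos < 1:
                raise ValueError("a 0/3-primary pair cannot reach 3/5 combined")
            if self.sign not in (1, -1):
                raise ValueError("final call requires a resolved sign")


def observations_to_frame(obs: Iterable[ReplicateObservation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "regulator": o.regulator_id,
                "reporter": o.reporter_id,
                "tier": o.tier,
                "replicate": o.replicate_index,
                "call": o.call,
            }
            for o in obs
        ],
        columns=["regulator", "reporter", "tier", "replicate", "call"],
    )


def _as_frame(observations) -> pd.DataFrame:
    if isinstance(observations, pd.DataFrame):
        return observations
    return observations_to_frame(observations)


def _positive_counts(tier_df: pd.DataFrame) -> "pd.Series[int]":
    pos = tier_df[tier_df["call"] != "none"]
    return pos.groupby(["regulator", "reporter"]).size()


def primary_candidates(observations) -> set[str]:
    """Regulators with any pair showing >= 2/3 non-``none`` primary calls.

    Counting ignores direction: any fluorescence change counts toward the
    2-of-3 rule.  Raises :class:`DataError` if a pair carries more than 3
    primary observations.
    """
    obs = _as_frame(observations)
    prim = obs[obs["tier"] == "primary"]
    n_obs = prim.groupby(["regulator", "reporter"]).size()
    if (n_obs > 3).any():
        bad = n_obs[n_obs > 3].index.tolist()[:5]
        raise DataError(f"more than 3 primary observations for pair(s): {bad}")
    pos = _positive_counts(prim)
    return set(pos[pos >= 2].index.get_level_values(0))


def combined_hits(observations) -> set[tuple[str, str]]:
    """Pairs passing the 3-of-5 combined (primary + retest) rule.

    Evaluated for *every* pair of a candidate regulator, including pairs at
    1/3 primary.  Raises :class:`ConsistencyError` if retest observations
    exist for a regulator that never triggered candidacy.
    """
    obs = _as_frame(observations)
    candidates = primary_candidates(obs)
    retest = obs[obs["tier"] == "retest"]
    stray = set(retest["regulator"]) - candidates
    if stray:
        raise ConsistencyError(
            f"retest observations for non-candidate regulator(s): {sorted(stray)[:5]}"
        )
    prim = obs[obs["tier"] == "primary"]
    prim_pairs = prim.groupby(["regulator", "reporter"]).size().index
    prim_pos = _positive_counts(prim)
    retest_pos = _positive_counts(retest)
    hits: set[tuple[str, str]] = set()
    for reg, rep in prim_pairs:
        if reg not in candidates:
            continue
        total = int(prim_pos.get((reg, rep), 0)) + int(retest_pos.get((reg, rep), 0))
        if total >= 3:
            hits.add((reg, rep))
    return hits


def sign_of_pair(calls: Sequence, imaging_calls: Sequence = ()) -> int:
    """Resolve an interaction's direction from its signed calls.

    ``calls`` is the multiset of calls across *all* tiers (strings
    ``increase``/``decrease`` or signs +1/-1; ``none``/0 entries are
    ignored), ``imaging_calls`` the imaging-tier subset used to break ties.
    Raises :class:`AmbiguousSignError` on a residual tie and ``ValueError``
    if no non-``none`` call is supplied.
    """
    signs = [_SIGN_OF_CALL[c] for c in calls]
    signs = [s for s in signs if s != 0]
    if not signs:
        raise ValueError("sign_of_pair requires at least one non-none call")
    total = sum(signs)
    if total != 0:
        return 1 if total > 0 else -1
    img = [_SIGN_OF_CALL[c] for c in imaging_calls]
    img_total = sum(s for s in img if s != 0)
    if img_total != 0:
        return 1 if img_total > 0 else -1
    raise AmbiguousSignError("tied increase/decrease calls, imaging tie-break failed")


def confirmed_interactions(
    observations,
    *,
    exclude_regulators: Iterable[str] = (),
    keep_ambiguous: bool = False,
) -> list[InteractionCall]:
    """Apply the full cascade and return one call per photographed pair.

    A pair is ``final`` iff it passed the combined rule and at least one of
    its two imaging replicates is non-``none``.  Regulators listed in
    ``exclude_regulators`` (e.g. clones outside the screened library that
    were only photographed) keep their evidence counts but are never marked
    final.  Ambiguous-direction pairs are dropped unless
    ``keep_ambiguous``, in which case they appear with ``sign = 0`` and
    ``final = False``.
    """
    obs = _as_frame(observations)
    hits = combined_hits(obs)
    imaging = obs[obs["tier"] == "imaging"]
    img_pairs = set(map(tuple, imaging[["regulator", "reporter"]].drop_duplicates().itertuples(index=False)))
    stray = img_pairs - hits
    if stray:
        raise ConsistencyError(
            f"imaging observations for pair(s) outside the combined hits: {sorted(stray)[:5]}"
        )
    excluded = set(exclude_regulators)
    nonnone = obs[obs["call"] != "none"]
    by_pair_tier = nonnone.groupby(["regulator", "reporter", "tier"])["call"]
    calls_lookup = {k: list(v) for k, v in by_pair_tier}
    img_pos = _positive_counts(imaging)

    results: list[InteractionCall] = []
    for reg, rep in sorted(hits):
        n_prim = len(calls_lookup.get((reg, rep, "primary"), ()))
        n_ret = len(calls_lookup.get((reg, rep, "retest"), ()))
        n_img = int(img_pos.get((reg, rep), 0))
        all_calls = (
            calls_lookup.get((reg, rep, "primary"), [])
            + calls_lookup.get((reg, rep, "retest"), [])
            + calls_lookup.get((reg, rep, "imaging"), [])
        )
        ambiguous = False
        try:
            sign = sign_of_pair(all_calls, calls_lookup.get((reg, rep, "imaging"), []))
        except AmbiguousSignError:
            ambiguous, sign = True, 0
        final = n_img >= 1 and not ambiguous and reg not in excluded
        if ambiguous and not keep_ambiguous:
            continue
        results.append(
            InteractionCall(
                regulator_id=reg,
                reporter_id=rep,
                sign=sign,
                n_primary_pos=n_prim,
                n_retest_pos=n_ret,
                n_photo_pos=n_img,
                final=final,
                ambiguous=ambiguous,
            )
        )
    return results


def _check_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {p}")


def cascade_sensitivity(p_primary: float, p_retest: float, p_photo: float) -> float:
    """P(final hit | true interaction), candidacy via this pair alone.

    With per-replicate detection probabilities ``p_primary`` (3 reps),
    ``p_retest`` (2 reps) and ``p_photo`` (2 reps):

        sum over a in {2, 3} of  P[Bin(3, p1) = a]
                               * P[Bin(2, p2) >= 3 - a]
                               * P[Bin(2, p3) >= 1]

    The a = 1 primary outcome never reaches retest here because candidacy
    requires 2 of 3 primary replicates on the pair itself.
    """
    _check_prob("p_primary", p_primary)
    _check_prob("p_retest", p_retest)
    _check_prob("p_photo", p_photo)
    p1, p2, p3 = p_primary, p_retest, p_photo
    prim2 = 3.0 * p1 * p1 * (1.0 - p1)
    prim3 = p1 ** 3
    retest_ge1 = 1.0 - (1.0 - p2) ** 2
    photo_ge1 = 1.0 - (1.0 - p3) ** 2
    return (prim2 * retest_ge1 + prim3) * photo_ge1


def cascade_specificity(q_fp: float) -> float:
    """P(false final hit | no interaction) with every tier calling at ``q_fp``.

    Same cascade formula with all three tier probabilities set to the
    per-replicate false-positive rate; conditional on the regulator having
    been retested.
    """
    _check_prob("q_fp", q_fp)
    return cascade_sensitivity(q_fp, q_fp, q_fp)


_CALL_COLUMNS = [
    "regulator",
    "reporter",
    "sign",
    "n_primary_pos",
    "n_retest_pos",
    "n_photo_pos",
    "final",
    "ambiguous",
]


def calls_to_frame(calls: Sequence[InteractionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "regulator": c.regulator_id,
                "reporter": c.reporter_id,
                "sign": c.sign,
                "n_primary_pos": c.n_primary_pos,
                "n_retest_pos": c.n_retest_pos,
                "n_photo_pos": c.n_photo_pos,
                "final": c.final,
                "ambiguous": c.ambiguous,
            }
            for c in calls
        ],
        columns=_CALL_COLUMNS,
    )


def write_calls(calls: Sequence[InteractionCall], path: str | Path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path) -> list[InteractionCall]:
    df = pd.read_csv(path, sep="\t")
    return [
        InteractionCall(
            regulator_id=row.regulator,
            reporter_id=row.reporter,
            sign=int(row.sign),
            n_primary_pos=int(row.n_primary_pos),
            n_retest_pos=int(row.n_retest_pos),
            n_photo_pos=int(row.n_photo_pos),
            final=bool(row.final),
            ambiguous=bool(row.ambiguous),
        )
        for row in df.itertuples(index=False)
    ]
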