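"""Condition-specific mechanism decomposition and qPCR quantification.

A promoter can be activated through several distinct physiological
conditions (here labelled mechanisms I, II and III, e.g. the three
metabolic perturbations that induce the acdh-1 promoter).  Regulators
required under each condition are scored as hit lists; this module merges
them into per-regulator profiles, partitions the regulators over the seven
Venn regions of the three mechanisms, and provides the delta-delta-Ct
computation used to verify knockdowns by qPCR.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MECHANISMS",
    "MechanismProfile",
    "QpcrSample",
    "venn_partition",
    "mechanism_membership",
    "ddct_fold_change",
    "read_hit_list",
    "read_ct_table",
    "write_venn_json",
]

MECHANISMS = ("I", "II", "III")


@dataclass(frozen=True)
class MechanismProfile:
    """Which activation mechanisms require one regulator."""

    regulator_id: str
    baseline_hit: bool
    required_in: frozenset[str]
    untestable: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for m in self.required_in | self.untestable:
            if m not in MECHANISMS:
                raise ValueError(f"unknown mechanism label {m!r}")


@dataclass(frozen=True)
class QpcrSample:
    """Replicate Ct values for a target gene plus endogenous controls."""

    sample_id: str
    target_ct: tuple[float, ...]
    control_cts: dict[str, tuple[float, ...]]

    def __post_init__(self) -> None:
        if not self.target_ct:
            raise ValueError(f"{self.sample_id}: empty target Ct replicate list")
        if not self.control_cts:
            raise ValueError(f"{self.sample_id}: no endogenous controls")
        for gene, cts in self.control_cts.items():
            if not cts:
                raise ValueError(f"{self.sample_id}: empty Ct list for control {gene}")
            if any(c <= 0 for c in cts):
                raise ValueError(f"{self.sample_id}: non-positive Ct for {gene}")
        if any(c <= 0 for c in self.target_ct):
            raise ValueError(f"{self.sample_id}: non-positive target Ct")


def mechanism_membership(
    baseline_hits: Iterable[str],
    condition_hits: Mapping[str, Iterable[str]],
    masked: Mapping[str, Iterable[str]] | None = None,
) -> list[MechanismProfile]:
    """Merge per-condition hit lists into per-regulator profiles.

    ``condition_hits`` maps mechanism labels (subset of I/II/III) to the
    regulators whose knockdown abolished activation under that condition.
    ``masked`` lists regulators that could not be assayed in a condition
    (e.g. the gene mutated to create the condition); they are flagged
    ``untestable`` there rather than scored absent.
    """
    bad = set(condition_hits) - set(MECHANISMS)
    if bad:
        raise ValueError(f"unknown mechanism label(s): {sorted(bad)}")
    masked = {m: set(v) for m, v in (masked or {}).items()}
    bad = set(masked) - set(MECHANISMS)
    if bad:
        raise ValueError(f"unknown mechanism label(s) in mask: {sorted(bad)}")
    baseline = set(baseline_hits)
    hit_sets = {m: set(v) for m, v in condition_hits.items()}
    universe = baseline | set().union(*hit_sets.values()) if hit_sets else set(baseline)
    profiles = []
    for reg in sorted(universe):
        required = {m for m, hits in hit_sets.items() if reg in hits}
        untestable = {m for m, msk in masked.items() if reg in msk}
        profiles.append(
            MechanismProfile(
                regulator_id=reg,
                baseline_hit=reg in baseline,
                required_in=frozenset(required - untestable),
                untestable=frozenset(untestable),
            )
        )
    return profiles


def venn_partition(
    profiles: Sequence[MechanismProfile],
) -> tuple[dict[frozenset[str], int], int]:
    """Count regulators in each of the 7 Venn regions of the mechanisms.

    Returns ``(region_counts, total)`` where the regions are the non-empty
    subsets of {I, II, III}; they partition the profiles with non-empty
    ``required_in`` and the counts sum to ``total``.
    """
    regions = {
        frozenset(s): 0
        for s in (
            {"I"}, {"II"}, {"III"},
            {"I", "II"}, {"I", "III"}, {"II", "III"},
            {"I", "II", "III"},
        )
    }
    total = 0
    for prof in profiles:
        if prof.required_in:
            regions[frozenset(prof.required_in)] += 1
            total += 1
    return regions, total


def _sample_delta_ct(sample: QpcrSample) -> float:
    # control Ct = arithmetic mean over control genes of their replicate
    # means (equivalent to geometric-mean normalisation of expression)
    control = float(np.mean([np.mean(cts) for cts in sample.control_cts.values()]))
    return float(np.mean(sample.target_ct)) - control


def ddct_fold_change(treated: QpcrSample, reference: QpcrSample) -> float:
    """Relative transcript abundance by the delta-delta-Ct method.

    ``fold = 2 ** -(dCt_treated - dCt_reference)`` where each sample's
    dCt is its mean target Ct minus the mean of its control genes' mean
    Cts.  Both samples must share the same control gene set.  A 4-fold
    knockdown returns ~0.25; identical samples return exactly 1.
    """
    if set(treated.control_cts) != set(reference.control_cts):
        raise ValueError(
            "treated and reference samples use different control gene sets: "
            f"{sorted(treated.control_cts)} vs {sorted(reference.control_cts)}"
        )
    ddct = _sample_delta_ct(treated) - _sample_delta_ct(reference)
    return float(2.0 ** (-ddct))


def read_hit_list(path: str | Path) -> set[str]:
    """Read a one-column (or first-column) TSV of regulator ids."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return set(df.iloc[:, 0].dropna())


def read_ct_table(path: str | Path) -> dict[str, QpcrSample]:
    """Read a long-format Ct table: sample, gene, role (target|control), ct."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "gene", "role", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing column(s): {sorted(missing)}")
    samples: dict[str, QpcrSample] = {}
    for sid, grp in df.groupby("sample"):
        target = tuple(grp.loc[grp["role"] == "target", "ct"].astype(float))
        controls = {
            gene: tuple(sub["ct"].astype(float))
            for gene, sub in grp[grp["role"] == "control"].groupby("gene")
        }
        samples[str(sid)] = QpcrSample(
            sample_id=str(sid), target_ct=target, control_cts=controls
        )
    return samples


def write_venn_json(
    profiles: Sequence[MechanismProfile], path: str | Path
) -> None:
    regions, total = venn_partition(profiles)
    payload = {
        "regions": {"+".join(sorted(k)): v for k, v in regions.items()},
        "total_with_any_mechanism": total,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
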