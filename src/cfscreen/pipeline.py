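"""End-to-end orchestration: simulate -> call -> network -> enrich.

A :class:`RunConfig` holds every tunable of a run (network shape, cascade
noise, analysis switches) plus one integer seed; per-stage substreams are
derived deterministically from it, so re-running the same config gives
byte-identical outputs, and every written artifact is listed with a sha256
digest in the JSON run report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

import cfscreen
from cfscreen.annotations import (
    GenomeBackground,
    library_summary,
    load_cofactor_table,
    records_to_frame,
)
from cfscreen.enrichment import (
    essentiality_enrichment,
    promoter_enrichment,
    tissue_enrichment,
    write_enrichment_tsv,
)
from cfscreen.hitcalling import confirmed_interactions, write_calls
from cfscreen.network import build_network, export_network, summary_fractions
from cfscreen.synthetic import (
    GroundTruthModel,
    NoiseModel,
    generate_cofactor_records,
    generate_ground_truth,
    simulate_replicates,
    write_ground_truth,
    write_observations,
)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

logger = logging.getLogger("cfscreen")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and context."""


@dataclass
class RunConfig:
    """Flat, validated configuration of one pipeline run."""

    out_dir: str = "cfscreen_run"
    seed: int = 0
    # ground-truth network shape
    n_regulators: int = 335
    n_promoters: int = 19
    density: float = 0.033
    decrease_fraction: float = 0.61
    hub_count: int = 1
    hub_out_degree: int = 14
    # cascade noise
    p_primary: float = 0.9
    p_retest: float = 0.9
    p_photo: float = 0.9
    q_fp: float = 0.005
    sign_flip: float = 0.0
    # annotations: path to a TSV, or empty to generate a synthetic table
    annotations: str = ""
    # enrichment switches
    directions: tuple[str, ...] = ("decrease", "increase")
    enrichment_background: str = "library"
    adjust_method: str = "fdr_bh"
    genome_genes: int = 19987
    genome_essential: int = 5996
    tissue: str = "intestine"

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "directions" in data:
            data = dict(data, directions=tuple(data["directions"]))
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def validate(self) -> None:
        if self.annotations and not Path(self.annotations).exists():
            raise FileNotFoundError(f"annotation table not found: {self.annotations}")
        for d in self.directions:
            if d not in ("increase", "decrease"):
                raise ValueError(f"unknown direction {d!r}")


def _scaled_sources(n_library: int) -> tuple[int, int, int]:
    """Split a library size into ORFeome/Ahringer/de-novo counts (~56/28/16)."""
    n_orf = round(n_library * 186 / 335)
    n_ahr = round(n_library * 95 / 335)
    return (n_orf, n_ahr, n_library - n_orf - n_ahr)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute all stages and return the provenance report (also written).

    Stages: simulate the planted network and replicate observations, call
    interactions through the cascade, assemble the network and its summary
    statistics, then (with an annotation table, synthetic by default) run
    the essentiality, per-promoter directional and tissue enrichments.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seed_truth, seed_noise, seed_annot = (
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3)
    )
    outputs: dict[str, Path] = {}

    @_stage("simulate")
    def _simulate():
        truth = generate_ground_truth(
            n_regulators=config.n_regulators,
            promoters=config.n_promoters,
            density=config.density,
            decrease_fraction=config.decrease_fraction,
            hub_spec=(config.hub_count, config.hub_out_degree)
            if config.hub_count
            else None,
            seed=seed_truth,
        )
        noise = NoiseModel(
            p_primary=config.p_primary,
            p_retest=config.p_retest,
            p_photo=config.p_photo,
            q_fp=config.q_fp,
            sign_flip=config.sign_flip,
            seed=seed_noise,
        )
        obs = simulate_replicates(truth, noise)
        write_ground_truth(truth, out / "ground_truth.tsv")
        write_observations(obs, out / "observations.tsv")
        outputs["ground_truth"] = out / "ground_truth.tsv"
        outputs["observations"] = out / "observations.tsv"
        return truth, obs

    truth, obs = _simulate()

    @_stage("call")
    def _call():
        calls = confirmed_interactions(obs)
        write_calls(calls, out / "calls.tsv")
        outputs["calls"] = out / "calls.tsv"
        return calls

    calls = _call()

    @_stage("netstats")
    def _netstats():
        net = build_network(calls, promoters=truth.promoters)
        for fmt, suffix in (("tsv", "network.tsv"), ("sif", "network.sif"), ("graphml", "network.graphml")):
            export_network(net, out / suffix, fmt)
            outputs[f"network_{fmt}"] = out / suffix
        summ = summary_fractions(net)
        (out / "network_summary.json").write_text(
            json.dumps(asdict(summ), indent=2, sort_keys=True) + "\n"
        )
        outputs["network_summary"] = out / "network_summary.json"
        return net

    net = _netstats()

    @_stage("annotations")
    def _annotations():
        if config.annotations:
            return load_cofactor_table(config.annotations)
        # synthetic table whose in-library genes are exactly the simulated
        # regulators (cf-0001 ... cf-NNNN), plus uncovered genes on top
        n_uncovered = round(config.n_regulators * 31 / 335)
        records = generate_cofactor_records(
            n_records=config.n_regulators + n_uncovered,
            clone_counts=None if config.n_regulators == 335 else _scaled_sources(config.n_regulators),
            shuffle_sources=False,
            seed=seed_annot,
        )
        frame = records_to_frame(records)
        frame.to_csv(out / "annotations.tsv", sep="\t", index=False)
        outputs["annotations"] = out / "annotations.tsv"
        return records

    records = _annotations()

    @_stage("enrich")
    def _enrich():
        background = GenomeBackground(
            n_genes=config.genome_genes, n_essential=config.genome_essential
        )
        ess = essentiality_enrichment(records, background, adjust=config.adjust_method)
        write_enrichment_tsv(ess, out / "enrichment_essentiality.tsv")
        outputs["enrichment_essentiality"] = out / "enrichment_essentiality.tsv"
        for direction in config.directions:
            res = promoter_enrichment(
                net,
                records,
                direction,
                background=config.enrichment_background,
                adjust=config.adjust_method,
            )
            p = out / f"enrichment_promoter_{direction}.tsv"
            write_enrichment_tsv(res, p)
            outputs[f"enrichment_promoter_{direction}"] = p
        known_tissues = set().union(*(r.tissues for r in records)) if records else set()
        if config.tissue in known_tissues:
            tis = tissue_enrichment(
                net, records, config.tissue, background=config.enrichment_background
            )
            p = out / "enrichment_tissue.tsv"
            write_enrichment_tsv([tis], p)
            outputs["enrichment_tissue"] = p

    _enrich()

    report: dict[str, Any] = {
        "version": cfscreen.__version__,
        "seed": config.seed,
        "stage_seeds": {
            "truth": seed_truth,
            "noise": seed_noise,
            "annotations": seed_annot,
        },
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "counts": {
            "planted_edges": len(truth.edges),
            "observations": int(len(obs)),
            "calls": len(calls),
            "final_edges": net.n_edges,
            "regulators_with_edges": len(net.regulators),
            "library_clones": library_summary(records).total_clones,
        },
        "outputs": {
            name: {"path": str(p), "sha256": _sha256(p), "bytes": p.stat().st_size}
            for name, p in sorted(outputs.items())
        },
    }
    (out / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
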