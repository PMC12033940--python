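"""Per-condition orchestration: build -> score -> propagate -> prioritize -> metrics.

A :class:`RunConfig` (usually loaded from YAML) names the reference
interactome, per-network protein universes, per-condition concentration
tables, the experimental cases, the top percentages and the propagation
parameters.  :func:`run_all` executes every condition, writes TSV/JSON
artefacts per stage, runs the declared cross-condition comparisons
(defaulting to each condition against its network's no-treatment
baseline) and returns an aggregate report.  Identical config + seed gives
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import yaml

from ppinet import io as pio
from ppinet.build import build_case_network, BuildReport
from ppinet.conditions import load_conditions, packaged_conditions
from ppinet.metrics import compute_metrics
from ppinet.prioritize import (
    PrioritizationResult,
    compare_conditions,
    categorize,
    select_top,
)
from ppinet.propagation import PropagationConfig, propagate, rank_nodes
from ppinet.scoring import ConditionSpec, score_ms_case, score_secretome_case

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_condition", "run_all"]


@dataclass
class RunConfig:
    """Everything one full multi-condition run needs."""

    reference: str
    universes: dict[str, str]
    outdir: str
    conditions: str | None = None  # YAML path; packaged catalogue when None
    concentrations: dict[str, str] = field(default_factory=dict)
    annotation: str | None = None
    min_confidence: float = 0.0
    top_percent: list[float] = field(default_factory=lambda: [5.0, 2.0])
    propagation: PropagationConfig = field(default_factory=PropagationConfig)
    rng_seed: int = 0
    include_seed_neighbourhood: bool = False
    unique_vs: str = "baseline"  # or "all": compare all conditions of a network at once
    contrasts: list[list[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.unique_vs not in {"baseline", "all"}:
            raise ValueError("unique_vs must be 'baseline' or 'all'")
        if not self.top_percent:
            raise ValueError("at least one top percentage is required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open() as fh:
            doc = yaml.safe_load(fh)
        prop = doc.pop("propagation", {})
        doc["propagation"] = PropagationConfig(**prop) if isinstance(prop, dict) else prop
        return cls(**doc)

    def load_condition_specs(self) -> list[ConditionSpec]:
        if self.conditions is None:
            return packaged_conditions()
        return load_conditions(self.conditions)


def _write_scores_tsv(path: Path, initial, ranking) -> None:
    init = initial.scores if hasattr(initial, "scores") else initial
    with path.open("w") as fh:
        fh.write("node\tinitial\tfinal\trank\n")
        for node, score, rank in ranking:
            fh.write(f"{node}\t{init.get(node, 0.0):.17g}\t{score:.17g}\t{rank}\n")


def run_condition(
    spec: ConditionSpec,
    reference: nx.Graph,
    universe: set[str],
    config: RunConfig,
    table: pio.ConcentrationTable | None = None,
    outdir: Path | None = None,
) -> tuple[PrioritizationResult, BuildReport, dict]:
    """Run one experimental case end to end.

    Returns the prioritization result, the build report and the metrics
    dict; writes the stage artefacts under ``outdir`` when given.
    """
    condition_proteins = set(spec.condition_proteins)
    if config.include_seed_neighbourhood:
        condition_proteins |= set(spec.seeds)
    net, report = build_case_network(reference, universe, condition_proteins)

    if spec.dataset_kind == "secretome":
        if table is None:
            raise ValueError(f"secretome condition {spec.name!r} needs a concentration table")
        initial = score_secretome_case(table, spec, net)
    else:
        initial = score_ms_case(spec, net)

    prop = propagate(net, initial, config.propagation)
    ranking = rank_nodes(prop)
    result = PrioritizationResult(condition=spec.name, ranking=ranking)
    for k in sorted(config.top_percent):
        result.top_sets[k] = select_top(ranking, k)
    metrics = compute_metrics(net, rng_seed=config.rng_seed).to_dict()

    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        pio.write_interactome(net, outdir / "network.tsv")
        _write_scores_tsv(outdir / "scores.tsv", initial, ranking)
        (outdir / "build_report.json").write_text(json.dumps(report.to_dict(), indent=1))
        (outdir / "metrics.json").write_text(json.dumps(metrics, indent=1))
        tops = {str(k): sorted(v) for k, v in result.top_sets.items()}
        (outdir / "top_candidates.json").write_text(json.dumps(tops, indent=1))
    return result, report, metrics


def _default_contrasts(specs: list[ConditionSpec]) -> list[list[str]]:
    """Each stimulated condition against its network's baseline."""
    out: list[list[str]] = []
    by_network: dict[str, list[ConditionSpec]] = {}
    for s in specs:
        by_network.setdefault(s.network or s.name, []).append(s)
    for network, members in by_network.items():
        baselines = [s for s in members if s.is_baseline]
        if not baselines:
            logger.warning("network %s has no baseline; skipping default contrasts", network)
            continue
        base = baselines[0]
        rest = [s for s in members if s.name != base.name]
        for s in rest:
            out.append([base.name, s.name])
    return out


def run_all(config: RunConfig) -> dict:
    """Run every condition and every contrast; return the aggregate report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference = pio.read_edge_list(config.reference, min_confidence=config.min_confidence)
    specs = config.load_condition_specs()
    annotation = pio.read_annotation(config.annotation) if config.annotation else None

    universes: dict[str, set[str]] = {
        key: pio.read_protein_list(path) for key, path in config.universes.items()
    }
    tables: dict[str, pio.ConcentrationTable] = {
        key: pio.read_concentrations(path) for key, path in config.concentrations.items()
    }

    report: dict = {"conditions": {}, "comparisons": [], "failed": {}}
    results: dict[str, PrioritizationResult] = {}
    for spec in specs:
        try:
            uni_key = spec.network if spec.network in universes else "default"
            if uni_key not in universes:
                raise ValueError(f"no universe for network {spec.network!r}")
            table = None
            if spec.dataset_kind == "secretome":
                table = tables.get(spec.name) or tables.get(spec.concentration_source or "")
                if table is None:
                    raise ValueError(f"no concentration table for {spec.name!r}")
            result, breport, metrics = run_condition(
                spec,
                reference,
                universes[uni_key],
                config,
                table=table,
                outdir=outdir / spec.name,
            )
            results[spec.name] = result
            entry = {
                "build": breport.to_dict(),
                "metrics": metrics,
                "top_counts": {str(k): len(v) for k, v in result.top_sets.items()},
            }
            if annotation is not None:
                k_min = min(result.top_sets)
                profile = categorize(result.top_sets[k_min], annotation)
                entry["categories"] = {
                    "k_percent": k_min,
                    "counts": profile.counts,
                    "unannotated": profile.unannotated,
                }
            report["conditions"][spec.name] = entry
        except Exception as exc:  # noqa: BLE001 — a failed case must not sink the run
            logger.exception("condition %s failed", spec.name)
            report["failed"][spec.name] = str(exc)

    contrasts = config.contrasts or (
        _default_contrasts(specs)
        if config.unique_vs == "baseline"
        else _grouped_contrasts(specs)
    )
    for group in contrasts:
        members = [results[name] for name in group if name in results]
        if len(members) < 2:
            continue
        for k in sorted(config.top_percent):
            cmp = compare_conditions(members, k)
            report["comparisons"].append(
                {
                    "conditions": cmp.conditions,
                    "k_percent": cmp.k_percent,
                    "shared": sorted(cmp.shared),
                    "unique": {c: sorted(u) for c, u in cmp.unique.items()},
                }
            )

    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def _grouped_contrasts(specs: list[ConditionSpec]) -> list[list[str]]:
    """All conditions of each network compared jointly (unique vs all siblings)."""
    by_network: dict[str, list[str]] = {}
    for s in specs:
        by_network.setdefault(s.network or s.name, []).append(s.name)
    return [names for names in by_network.values() if len(names) >= 2]
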