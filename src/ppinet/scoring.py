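"""Initial seed scores for each experimental case.

Two scoring schemes are supported, matching the two kinds of proteomic
input:

* mass-spectrometry cases: binary — each seed protein scores 1, every
  other node 0, and the stimulating interleukins additionally score 1
  under their conditions;
* secretome cases: replicate concentrations are averaged, min-max scaled
  over the measured analyte panel, ``Xsc = (X - Xmin) / (Xmax - Xmin)``,
  restricted to the network (unmeasured nodes score 0), and each stimulus
  protein is forced to 1 — the score of the most expressed protein — to
  emphasise the in-vitro/ex-vivo stimulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx

from ppinet.io import ConcentrationTable

__all__ = [
    "ConditionSpec",
    "ScoreVector",
    "minmax_scale",
    "score_secretome_case",
    "score_ms_case",
]

DATASET_KINDS = ("secretome", "mass_spec")


@dataclass
class ConditionSpec:
    """One experimental case: dataset, phenotype, seeds and stimuli.

    ``seeds`` are the baseline proteins of interest (e.g. the most
    expressed secreted protein, or a literature-curated panel);
    ``stimuli`` are the stimulating cytokines added under treatment
    conditions (IL4, IL10, IL1B, alone or combined).
    """

    name: str
    dataset_kind: str
    seeds: list[str]
    stimuli: list[str] = field(default_factory=list)
    phenotype: str = ""
    network: str = ""
    concentration_source: str | None = None

    def __post_init__(self) -> None:
        if self.dataset_kind not in DATASET_KINDS:
            raise ValueError(
                f"dataset_kind must be one of {DATASET_KINDS}, got {self.dataset_kind!r}"
            )
        self.seeds = [s.strip().upper() for s in self.seeds]
        self.stimuli = [s.strip().upper() for s in self.stimuli]
        if not self.seeds:
            raise ValueError(f"condition {self.name!r} has no seeds")
        if self.dataset_kind == "secretome" and self.concentration_source is None:
            raise ValueError(
                f"secretome condition {self.name!r} requires a concentration_source"
            )

    @property
    def condition_proteins(self) -> set[str]:
        """Proteins added to the network for this condition (the stimuli)."""
        return set(self.stimuli)

    @property
    def is_baseline(self) -> bool:
        return not self.stimuli


@dataclass
class ScoreVector:
    """Node -> score map in [0, 1] with a provenance tag."""

    scores: dict[str, float]
    provenance: str = "binary"

    def __post_init__(self) -> None:
        bad = {n: v for n, v in self.scores.items() if not 0.0 <= v <= 1.0}
        if bad:
            raise ValueError(f"scores outside [0,1]: {dict(list(bad.items())[:5])}")

    def __getitem__(self, node: str) -> float:
        return self.scores[node]

    def get(self, node: str, default: float = 0.0) -> float:
        return self.scores.get(node, default)

    def __len__(self) -> int:
        return len(self.scores)

    def nonzero(self) -> set[str]:
        return {n for n, v in self.scores.items() if v > 0}


def minmax_scale(values: dict[str, float]) -> dict[str, float]:
    """Min-max scale a protein -> value map to [0, 1].

    Each output is ``(X - Xmin) / (Xmax - Xmin)``.  When all inputs are
    equal the denominator vanishes; every output is then 0 and a
    degenerate-input warning is raised.
    """
    if not values:
        raise ValueError("cannot scale an empty value map")
    if any(v < 0 for v in values.values()):
        raise ValueError("negative values are not allowed")
    xmin = min(values.values())
    xmax = max(values.values())
    if xmax == xmin:
        warnings.warn("degenerate input: all values equal; scaled scores are all 0", stacklevel=2)
        return {p: 0.0 for p in values}
    span = xmax - xmin
    return {p: (x - xmin) / span for p, x in values.items()}


def score_secretome_case(
    table: ConcentrationTable, spec: ConditionSpec, net: nx.Graph
) -> ScoreVector:
    """Concentration-derived seed scores for a secretome case.

    Replicates are averaged per protein, min-max scaled over the measured
    panel (before restriction to the network), unmeasured network nodes
    score 0, and each stimulus protein is overwritten to 1.0.
    """
    if spec.dataset_kind != "secretome":
        raise ValueError(f"{spec.name!r} is not a secretome condition")
    missing_stimuli = [s for s in spec.stimuli if s not in net]
    if missing_stimuli:
        raise ValueError(
            f"stimulus proteins absent from the network: {missing_stimuli}; "
            "they must be added during network construction"
        )
    scaled = minmax_scale(table.replicate_means())
    scores = {n: 0.0 for n in net.nodes}
    for p, v in scaled.items():
        if p in scores:
            scores[p] = v
    for s in spec.stimuli:
        scores[s] = 1.0
    return ScoreVector(scores=scores, provenance="scaled_concentration")


def score_ms_case(spec: ConditionSpec, net: nx.Graph) -> ScoreVector:
    """Binary seed scores for a mass-spectrometry case.

    Seeds present in the network score 1 (absent seeds are warned about
    and skipped), stimuli score 1, all other nodes 0.
    """
    if spec.dataset_kind != "mass_spec":
        raise ValueError(f"{spec.name!r} is not a mass_spec condition")
    present = [s for s in spec.seeds if s in net]
    absent = [s for s in spec.seeds if s not in net]
    if absent:
        warnings.warn(f"seeds absent from network, skipped: {absent}", stacklevel=2)
    if not present:
        raise ValueError(f"no seed of condition {spec.name!r} occurs in the network")
    missing_stimuli = [s for s in spec.stimuli if s not in net]
    if missing_stimuli:
        raise ValueError(
            f"stimulus proteins absent from the network: {missing_stimuli}"
        )
    scores = {n: 0.0 for n in net.nodes}
    for s in present:
        scores[s] = 1.0
    for s in spec.stimuli:
        scores[s] = 1.0
    return ScoreVector(scores=scores, provenance="binary")
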