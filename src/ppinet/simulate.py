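"""Synthetic inputs with known ground truth.

No raw interactome, secretome panel or mass-spectrometry universe is
distributed with the studies this pipeline targets, so every input can be
generated here with a planted structure that downstream stages must
recover:

* a planted-partition (stochastic block model) interactome — within each
  of ``n_communities`` blocks edges appear with probability ``p_in``,
  between blocks with ``p_out`` — with one block designated the disease
  module and a handful of true seed proteins drawn from it;
* a Luminex-style secretome panel (default 73 analytes x 3 replicates) of
  right-skewed log-normal concentrations with per-protein multiplicative
  condition effects;
* a mass-spectrometry-style universe of ~14k protein identifiers
  containing any required seed panel.

Everything is bit-reproducible for a given ``rng_seed``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np

from ppinet.io import ConcentrationTable
from ppinet.metrics import Partition

__all__ = [
    "SyntheticGroundTruth",
    "generate_interactome",
    "generate_secretome_panel",
    "generate_ms_universe",
]


@dataclass
class SyntheticGroundTruth:
    """What was planted: communities, the disease module, the true seeds."""

    partition: Partition
    disease_module: int
    true_seeds: set[str]
    params: dict = field(default_factory=dict)

    def module_nodes(self) -> set[str]:
        return {
            n for n, c in self.partition.membership.items() if c == self.disease_module
        }

    def to_dict(self) -> dict:
        d = asdict(self)
        d["true_seeds"] = sorted(self.true_seeds)
        return d


def generate_interactome(
    n_nodes: int = 400,
    n_communities: int = 4,
    p_in: float = 0.3,
    p_out: float = 0.01,
    rng_seed: int = 0,
    n_seeds: int = 5,
    disease_module: int = 0,
) -> tuple[nx.Graph, SyntheticGroundTruth]:
    """Planted-partition interactome with uniform [0.5, 1] edge confidences.

    Nodes ``P0000..`` are split into ``n_communities`` near-equal blocks.
    ``n_seeds`` true seed proteins are drawn uniformly from the designated
    disease module.  Parameter combinations whose expected within-block
    degree is too small to keep the graph connected are allowed but
    flagged with a warning.
    """
    if not 0 <= p_out < p_in <= 1:
        raise ValueError("require 0 <= p_out < p_in <= 1")
    if n_nodes < n_communities:
        raise ValueError("need at least one node per community")
    if not 0 <= disease_module < n_communities:
        raise ValueError("disease_module out of range")

    rng = np.random.default_rng(rng_seed)
    nodes = [f"P{i:04d}" for i in range(n_nodes)]
    membership = {nodes[i]: i % n_communities for i in range(n_nodes)}

    g = nx.Graph(name=f"planted_sbm_n{n_nodes}_k{n_communities}")
    g.add_nodes_from(nodes)
    # row-chunked Bernoulli draws keep memory linear in n
    comm = np.array([membership[n] for n in nodes])
    for i in range(n_nodes - 1):
        m = n_nodes - i - 1
        p = np.where(comm[i + 1 :] == comm[i], p_in, p_out)
        hits = np.nonzero(rng.random(m) < p)[0]
        confs = rng.uniform(0.5, 1.0, size=hits.size)
        for j, c in zip(hits, confs):
            g.add_edge(nodes[i], nodes[i + 1 + j], confidence=float(c))

    block = n_nodes // n_communities
    if p_in * (block - 1) < np.log(max(block, 2)):
        warnings.warn(
            "expected within-community degree is below the connectivity "
            "threshold; the generated graph may be disconnected",
            stacklevel=2,
        )

    module = sorted(n for n, c in membership.items() if c == disease_module)
    n_seeds = min(n_seeds, len(module))
    seeds = set(rng.choice(module, size=n_seeds, replace=False).tolist())
    truth = SyntheticGroundTruth(
        partition=Partition(membership=membership),
        disease_module=disease_module,
        true_seeds=seeds,
        params={
            "n_nodes": n_nodes,
            "n_communities": n_communities,
            "p_in": p_in,
            "p_out": p_out,
            "rng_seed": rng_seed,
            "n_seeds": n_seeds,
        },
    )
    return g, truth


def generate_secretome_panel(
    n_proteins: int = 73,
    n_replicates: int = 3,
    condition_effects: dict[str, float] | None = None,
    rng_seed: int = 0,
    proteins: list[str] | None = None,
    baseline_location: float = np.log(100.0),
    baseline_sigma: float = 1.5,
    replicate_sigma: float = 0.2,
    condition: str = "baseline",
) -> ConcentrationTable:
    """Log-normal multiplex-immunoassay panel with condition effects.

    Baseline per-protein concentrations are log-normal (location/scale as
    given, nominal pg/ml); each replicate multiplies the baseline by the
    protein's condition effect (default 1) and log-normal replicate noise.
    Analyte names default to ``SEC001..`` but an explicit protein list
    (e.g. interactome node names) may be supplied.
    """
    if proteins is not None:
        proteins = [p.strip().upper() for p in proteins]
        n_proteins = len(proteins)
    else:
        proteins = [f"SEC{i + 1:03d}" for i in range(n_proteins)]
    effects = {p.strip().upper(): e for p, e in (condition_effects or {}).items()}
    if any(e <= 0 for e in effects.values()):
        raise ValueError("condition effects must be positive")

    rng = np.random.default_rng(rng_seed)
    baseline = rng.lognormal(mean=baseline_location, sigma=baseline_sigma, size=n_proteins)
    effect = np.array([effects.get(p, 1.0) for p in proteins])
    noise = rng.lognormal(mean=0.0, sigma=replicate_sigma, size=(n_proteins, n_replicates))
    values = baseline[:, None] * effect[:, None] * noise
    return ConcentrationTable(proteins=proteins, values=values, condition=condition)


def generate_ms_universe(
    n_proteins: int = 14000,
    must_include: set[str] | None = None,
    rng_seed: int = 0,
) -> set[str]:
    """Mass-spectrometry-style protein universe of exactly ``n_proteins`` ids.

    ``must_include`` (e.g. a curated seed panel) is always contained in
    the result; the remainder are synthetic ``MS`` identifiers drawn
    deterministically from ``rng_seed``.
    """
    must_include = {p.strip().upper() for p in (must_include or set())}
    if len(must_include) > n_proteins:
        raise ValueError("must_include larger than the requested universe")
    rng = np.random.default_rng(rng_seed)
    universe = set(must_include)
    # draw from a pool comfortably larger than needed so collisions are cheap
    pool_size = max(2 * n_proteins, 1000)
    while len(universe) < n_proteins:
        needed = n_proteins - len(universe)
        draws = rng.integers(0, pool_size, size=2 * needed + 10)
        for d in draws:
            universe.add(f"MS{int(d):06d}")
            if len(universe) == n_proteins:
                break
    return universe
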