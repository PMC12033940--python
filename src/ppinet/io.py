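"""Readers and writers for interactomes and tabular pipeline inputs.

The on-disk interactome format is a HIPPIE-style tab-delimited edge list:
``idA<TAB>idB<TAB>confidence`` with optional ``#`` comment lines.  In
memory an interactome is an undirected :class:`networkx.Graph` whose nodes
are uppercase gene symbols and whose edges carry a ``confidence``
attribute in [0, 1].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ConcentrationTable",
    "read_edge_list",
    "read_protein_list",
    "read_concentrations",
    "read_id_map",
    "read_annotation",
    "write_interactome",
]


@dataclass
class ConcentrationTable:
    """Replicate-level protein concentrations for one experimental condition.

    Parameters
    ----------
    proteins
        Analyte identifiers, unique, uppercase.
    values
        ``(n_proteins, n_replicates)`` nonnegative array of concentrations
        (nominally pg/ml).
    condition
        Label of the condition the replicates belong to.
    """

    proteins: list[str]
    values: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D protein x replicate array")
        if len(self.proteins) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.proteins)} proteins but {self.values.shape[0]} rows"
            )
        if self.values.shape[1] < 1:
            raise ValueError("at least one replicate is required")
        if len(set(self.proteins)) != len(self.proteins):
            dupes = sorted({p for p in self.proteins if self.proteins.count(p) > 1})
            raise ValueError(f"duplicate protein rows: {dupes[:5]}")
        if np.isnan(self.values).any():
            raise ValueError("missing concentration values are not allowed")
        if (self.values < 0).any():
            raise ValueError("negative concentration values are not allowed")

    @property
    def n_replicates(self) -> int:
        return self.values.shape[1]

    def replicate_means(self) -> dict[str, float]:
        """Arithmetic mean over replicates, per protein."""
        means = self.values.mean(axis=1)
        return dict(zip(self.proteins, means.tolist()))

    def to_frame(self) -> pd.DataFrame:
        cols = [f"rep{i + 1}" for i in range(self.n_replicates)]
        return pd.DataFrame(self.values, index=pd.Index(self.proteins, name="protein"), columns=cols)


def _canonical(symbol: str) -> str:
    return symbol.strip().upper()


def read_id_map(path: str | Path) -> dict[str, str]:
    """Read a two-column ``source<TAB>symbol`` identifier map.

    Symbols are upper-cased; the mapping may be many-to-one but every
    canonical symbol must be non-empty.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    entries: dict[str, str] = {}
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[1].strip():
                raise ValueError(f"malformed id-map line: {line!r}")
            entries[parts[0].strip()] = _canonical(parts[1])
    return entries


def read_annotation(path: str | Path) -> dict[str, str]:
    """Read a two-column ``protein<TAB>category`` annotation table.

    A local stand-in for knowledgebase lookups; the category vocabulary is
    whatever the file supplies.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    entries: dict[str, str] = {}
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[1].strip():
                raise ValueError(f"malformed annotation line: {line!r}")
            entries[_canonical(parts[0])] = parts[1].strip()
    return entries


def read_edge_list(
    path: str | Path,
    id_map: dict[str, str] | None = None,
    min_confidence: float = 0.0,
    name: str | None = None,
) -> nx.Graph:
    """Read a scored undirected interactome from a tab-delimited edge list.

    Rows are ``idA<TAB>idB<TAB>confidence``; extra columns are ignored and
    ``#`` lines are comments.  Self-loops are dropped, duplicate pairs are
    collapsed keeping the maximum confidence, rows below ``min_confidence``
    or with malformed confidences are rejected (and counted in the log),
    and identifiers are passed through ``id_map`` when one is given (rows
    with unmappable identifiers are dropped).

    Returns
    -------
    networkx.Graph
        Deduplicated undirected graph with per-edge ``confidence``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if not 0.0 <= min_confidence:
        raise ValueError("min_confidence must be nonnegative")

    g = nx.Graph(name=name or path.stem)
    n_rejected = n_unmapped = n_self = n_below = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("#node\t"):
                # isolated-node record emitted by write_interactome
                node = _canonical(line.split("\t", 1)[1])
                if node:
                    g.add_node(node)
                continue
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                n_rejected += 1
                logger.debug("line %d: fewer than 3 columns", lineno)
                continue
            a, b, conf_str = parts[0].strip(), parts[1].strip(), parts[2].strip()
            try:
                conf = float(conf_str)
            except ValueError:
                n_rejected += 1
                logger.debug("line %d: non-numeric confidence %r", lineno, conf_str)
                continue
            if not 0.0 <= conf <= 1.0 or not np.isfinite(conf):
                n_rejected += 1
                logger.debug("line %d: confidence %r outside [0,1]", lineno, conf_str)
                continue
            if id_map is not None:
                if a not in id_map or b not in id_map:
                    n_unmapped += 1
                    continue
                a, b = id_map[a], id_map[b]
            a, b = _canonical(a), _canonical(b)
            if not a or not b:
                n_rejected += 1
                continue
            if a == b:
                n_self += 1
                continue
            if conf < min_confidence:
                n_below += 1
                continue
            if g.has_edge(a, b):
                if conf > g.edges[a, b]["confidence"]:
                    g.edges[a, b]["confidence"] = conf
            else:
                g.add_edge(a, b, confidence=conf)

    if n_rejected or n_unmapped or n_self or n_below:
        logger.info(
            "%s: rejected %d malformed, %d unmappable, %d self-loop, %d sub-threshold rows",
            path.name,
            n_rejected,
            n_unmapped,
            n_self,
            n_below,
        )
    if g.number_of_edges() == 0:
        warnings.warn(f"no edges survived parsing {path}", stacklevel=2)
    return g


def read_protein_list(path: str | Path) -> set[str]:
    """Read a one-identifier-per-line protein universe.

    Blank lines and ``#`` comments are skipped; identifiers are upper-cased
    and deduplicated.  An empty result is an error — a universe of zero
    proteins cannot define a network.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: set[str] = set()
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            out.add(_canonical(line))
    if not out:
        raise ValueError(f"protein list {path} contains no identifiers")
    return out


def read_concentrations(path: str | Path, condition: str = "") -> ConcentrationTable:
    """Read a replicate x protein concentration TSV.

    Expected layout: a header row, first column the protein identifier,
    remaining columns one biological replicate each.  Values must be
    nonnegative and complete; duplicate protein rows are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 1:
        raise ValueError(f"{path}: no replicate columns found")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric concentration value ({exc})") from exc
    proteins = [_canonical(str(p)) for p in df.index]
    return ConcentrationTable(proteins=proteins, values=values, condition=condition or path.stem)


def write_interactome(net: nx.Graph, path: str | Path, format: str = "tsv") -> None:
    """Write an interactome as an edge-list TSV or GraphML.

    The TSV round-trips exactly through :func:`read_edge_list` (node set,
    edge set, confidences); isolated nodes are preserved via comment lines
    of the form ``#node<TAB><id>``.
    """
    path = Path(path)
    if format not in {"tsv", "graphml"}:
        raise ValueError(f"unknown format {format!r}; use 'tsv' or 'graphml'")
    if format == "graphml":
        nx.write_graphml(net, path)
        return
    with path.open("w") as fh:
        fh.write("#idA\tidB\tconfidence\n")
        for u, v, data in sorted(net.edges(data=True), key=lambda e: (min(e[0], e[1]), max(e[0], e[1]))):
            a, b = sorted((u, v))
            fh.write(f"{a}\t{b}\t{data.get('confidence', 1.0):.17g}\n")
        for node in sorted(net.nodes):
            if net.degree(node) == 0:
                fh.write(f"#node\t{node}\n")
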