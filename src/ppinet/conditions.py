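"""The packaged catalogue of experimental cases.

``data/conditions.yaml`` encodes the five study networks (trauma,
degenerated and explant secretome networks; young and old MS networks)
and their stimulation conditions as :class:`~ppinet.scoring.ConditionSpec`
objects.  The same YAML schema can describe user-supplied designs.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from ppinet.scoring import ConditionSpec

__all__ = ["load_conditions", "packaged_conditions"]


def _parse(doc: dict) -> list[ConditionSpec]:
    specs: list[ConditionSpec] = []
    networks = doc.get("networks")
    if not networks:
        raise ValueError("condition file has no 'networks' section")
    for net_name, net in networks.items():
        kind = net["dataset_kind"]
        seeds = list(net["seeds"])
        phenotype = net.get("phenotype", "")
        source = net.get("concentration_source")
        if kind == "secretome" and source is None:
            source = net_name  # key into the pipeline's concentration tables
        for cond_name, stimuli in net.get("conditions", {}).items():
            specs.append(
                ConditionSpec(
                    name=f"{net_name}_{cond_name}",
                    dataset_kind=kind,
                    seeds=seeds,
                    stimuli=list(stimuli or []),
                    phenotype=phenotype,
                    network=net_name,
                    concentration_source=source,
                )
            )
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("condition names are not unique")
    return specs


def load_conditions(path: str | Path) -> list[ConditionSpec]:
    """Load condition specs from a YAML file (see the packaged example)."""
    with Path(path).open() as fh:
        return _parse(yaml.safe_load(fh))


def packaged_conditions() -> list[ConditionSpec]:
    """The packaged study design: 20 cases over five networks."""
    ref = resources.files("ppinet").joinpath("data/conditions.yaml")
    return _parse(yaml.safe_load(ref.read_text()))
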