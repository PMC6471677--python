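"""Reading and writing the package's on-disk formats.

Cohorts are CSV pairs (``statics.csv`` with one row per patient including a
``death_day`` column; ``visits.csv`` with one row per visit) plus an optional
``alsfrsr.csv`` item table and a ``variables.yaml`` schema.  Fitted models are
saved as a JSON document (structure, CPTs, schema, provenance) together with
GraphML and DOT renderings of the DAG for inspection in graph tools.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .cohort import PID, Cohort
from .dbn import CpdSet, DbnModel, DbnStructure, FittedDbn
from .specs import NodeDef, Role, VariableSpec, specs_from_dict, specs_to_dict

# ---------------------------------------------------------------------------
# cohorts


def save_cohort(cohort: Cohort, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    statics = cohort.statics.copy()
    statics["death_day"] = cohort.death_day
    statics.to_csv(d / "statics.csv", index_label=PID)
    cohort.visits.to_csv(d / "visits.csv", index=False)
    if cohort.alsfrsr is not None:
        cohort.alsfrsr.to_csv(d / "alsfrsr.csv", index=False)


def load_cohort(directory: str | Path) -> Cohort:
    d = Path(directory)
    statics = pd.read_csv(d / "statics.csv", index_col=PID)
    death = statics.pop("death_day")
    visits = pd.read_csv(d / "visits.csv")
    alsfrsr_path = d / "alsfrsr.csv"
    alsfrsr = pd.read_csv(alsfrsr_path) if alsfrsr_path.exists() else None
    return Cohort(statics=statics, visits=visits, death_day=death, alsfrsr=alsfrsr)


def save_variables(specs: Sequence[VariableSpec], path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump({"variables": specs_to_dict(specs)}, sort_keys=False))


def load_variables(path: str | Path) -> list[VariableSpec]:
    doc = yaml.safe_load(Path(path).read_text())
    return specs_from_dict(doc["variables"])


# ---------------------------------------------------------------------------
# models


def model_to_json_dict(model: DbnModel) -> dict:
    return {
        "nodes": [
            {"name": n.name, "role": n.role.value, "cardinality": n.cardinality, "base": n.base}
            for n in model.structure.nodes
        ],
        "parents": {c: list(ps) for c, ps in sorted(model.structure.parents.items())},
        "tables": {k: v.tolist() for k, v in sorted(model.cpds.tables.items())},
        "alpha": model.cpds.alpha,
        "tso_cuts": list(model.tso_cuts),
        "variables": specs_to_dict(model.specs),
    }


def save_model(model: DbnModel, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    doc = model_to_json_dict(model)
    if isinstance(model, FittedDbn) and model.ledger is not None:
        doc["provenance"] = model.provenance()
        model.ledger.to_frame().to_csv(d / "score_ledger.csv", index=False)
    (d / "model.json").write_text(json.dumps(doc, indent=1, sort_keys=True))
    g = structure_to_graphml(model.structure)
    nx.write_graphml(g, d / "structure.graphml")
    (d / "structure.dot").write_text(structure_to_dot(model.structure))


def load_model(directory: str | Path) -> DbnModel:
    d = Path(directory)
    doc = json.loads((d / "model.json").read_text())
    nodes = tuple(
        NodeDef(n["name"], Role(n["role"]), int(n["cardinality"]), n.get("base", ""))
        for n in doc["nodes"]
    )
    structure = DbnStructure(nodes=nodes, parents={c: tuple(p) for c, p in doc["parents"].items()})
    cards = {n.name: n.cardinality for n in nodes}
    cpds = CpdSet(
        tables={k: np.asarray(v, dtype=float) for k, v in doc["tables"].items()},
        parents=dict(structure.parents),
        cards=cards,
        alpha=float(doc["alpha"]),
    )
    return DbnModel(
        structure=structure,
        cpds=cpds,
        specs=specs_from_dict(doc["variables"]),
        tso_cuts=tuple(doc["tso_cuts"]),
    )


_ROLE_SLICE = {
    Role.L1: "static", Role.L2: "static", Role.L3: "static",
    Role.PREV: "t-1", Role.CUR: "t", Role.TSO: "t", Role.DEATH: "survival",
}
_ROLE_LAYER = {
    Role.L1: 1, Role.L2: 2, Role.L3: 3, Role.PREV: 4, Role.CUR: 5, Role.TSO: 5, Role.DEATH: 6,
}


def structure_to_graphml(structure: DbnStructure) -> nx.DiGraph:
    g = nx.DiGraph()
    for n in structure.nodes:
        g.add_node(
            n.name,
            layer=_ROLE_LAYER[n.role],
            slice=_ROLE_SLICE[n.role],
            cardinality=n.cardinality,
        )
    g.add_edges_from(structure.edges())
    return g


def structure_to_dot(structure: DbnStructure) -> str:
    lines = ["digraph dbn {"]
    for n in structure.nodes:
        lines.append(
            f'  "{n.name}" [layer={_ROLE_LAYER[n.role]} cardinality={n.cardinality}];'
        )
    for p, c in structure.edges():
        lines.append(f'  "{p}" -> "{c}";')
    lines.append("}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# misc outputs


def save_json(obj: Mapping, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=_jsonable))


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, pd.DataFrame):
        return x.to_dict()
    raise TypeError(f"not JSON-serializable: {type(x)}")
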