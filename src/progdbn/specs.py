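"""Variable schemas, discretization rules and the layered edge mask.

Variables live in six strata that constrain which directed edges a learned
network may contain: demographic statics (layer 1), onset descriptors
(layer 2), treatment statics (layer 3), dynamic measurements at the previous
time slice (layer 4) and at the current slice (layer 5, which also carries
cumulative time since onset, TSO), and the survival indicator (layer 6).
Edges may only run from lower to higher layers, with slice-(t) variables
additionally allowed to influence each other (acyclically).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

MISSING = -1  # sentinel code for a missing categorical value

STATIC_LAYERS = (1, 2, 3)
DYNAMIC_LAYERS = (4, 5)


class Quantization:
    """Base class for discretization rules mapping raw values to codes."""

    cardinality: int

    def encode(self, values: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


@dataclass(frozen=True)
class ClinicalThresholds(Quantization):
    """Ordinal binning at fixed, clinically meaningful cut points.

    Bins are half-open ``[low, high)``: a value exactly equal to a cut point
    falls in the upper bin.  With cuts ``(51, 61)`` the codes are
    ``x < 51 -> 0``, ``51 <= x < 61 -> 1``, ``x >= 61 -> 2``.
    """

    cuts: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.cuts) < 1:
            raise ValueError("need at least one cut point")
        if any(b <= a for a, b in zip(self.cuts, self.cuts[1:])):
            raise ValueError(f"cut points must be strictly increasing: {self.cuts}")

    @property
    def cardinality(self) -> int:
        return len(self.cuts) + 1

    def encode(self, values: np.ndarray) -> np.ndarray:
        vals = np.asarray(values, dtype=float)
        codes = np.searchsorted(np.asarray(self.cuts), vals, side="right")
        return np.where(np.isfinite(vals), codes, MISSING).astype(np.int64)


@dataclass(frozen=True)
class Tertiles(Quantization):
    """Equal-mass three-level binning with cuts estimated from training data.

    Cut points are the order statistics at ranks ``floor(n/3)`` and
    ``floor(2n/3)`` of the sorted training values (the smallest value of the
    middle and upper third), so that for ``n`` divisible by 3 each bin holds
    exactly a third of the training sample.  Encoding then follows the same
    half-open convention as :class:`ClinicalThresholds`.
    """

    cuts: tuple[float, float] | None = None

    @property
    def cardinality(self) -> int:
        return 3

    def fit(self, training_values: np.ndarray) -> "Tertiles":
        vals = np.asarray(training_values, dtype=float)
        vals = np.sort(vals[np.isfinite(vals)])
        n = vals.size
        if n < 3:
            raise ValueError("need at least 3 observed training values for tertiles")
        lo, hi = float(vals[n // 3]), float(vals[(2 * n) // 3])
        if not lo < hi:
            # degenerate (heavily tied) distribution: nudge to keep bins ordered
            hi = np.nextafter(lo, np.inf)
        return Tertiles(cuts=(lo, hi))

    def encode(self, values: np.ndarray) -> np.ndarray:
        if self.cuts is None:
            raise ValueError("tertile cuts not fitted; call fit() on training data")
        return ClinicalThresholds(self.cuts).encode(values)


@dataclass(frozen=True)
class Categorical(Quantization):
    """Nominal variable with an explicit, ordered label set."""

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) < 2:
            raise ValueError("categorical variable needs >= 2 labels")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate categorical labels")

    @property
    def cardinality(self) -> int:
        return len(self.labels)

    def encode(self, values: np.ndarray) -> np.ndarray:
        lut = {lab: i for i, lab in enumerate(self.labels)}
        out = np.empty(len(values), dtype=np.int64)
        for i, v in enumerate(values):
            if v is None or (isinstance(v, float) and np.isnan(v)):
                out[i] = MISSING
            else:
                key = v if isinstance(v, str) else str(v)
                if key not in lut and not isinstance(v, str):
                    # allow raw integer codes already in range
                    iv = int(v)
                    if 0 <= iv < len(self.labels):
                        out[i] = iv
                        continue
                if key not in lut:
                    raise ValueError(f"value {v!r} not among labels {self.labels}")
                out[i] = lut[key]
        return out


@dataclass(frozen=True)
class VariableSpec:
    """Schema entry for one cohort variable.

    Parameters
    ----------
    name
        Column name in the cohort tables.
    kind
        ``"static"`` (one value per patient) or ``"dynamic"`` (one per visit).
    layer
        Stratum 1-6; must be consistent with ``kind`` (1-3 and 6 static,
        4-5 dynamic).
    quantization
        Discretization rule; determines the variable's cardinality.
    units
        Free-text measurement units, informational only.
    """

    name: str
    kind: str
    layer: int
    quantization: Quantization
    units: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("static", "dynamic"):
            raise ValueError(f"kind must be static|dynamic, got {self.kind!r}")
        if not 1 <= self.layer <= 6:
            raise ValueError(f"layer must be 1..6, got {self.layer}")
        if self.kind == "static" and self.layer in DYNAMIC_LAYERS:
            raise ValueError(f"{self.name}: static variable cannot sit in layer {self.layer}")
        if self.kind == "dynamic" and self.layer not in DYNAMIC_LAYERS:
            raise ValueError(f"{self.name}: dynamic variable must sit in layer 4 or 5")
        if self.cardinality < 2:
            raise ValueError(f"{self.name}: cardinality must be >= 2")

    @property
    def cardinality(self) -> int:
        return self.quantization.cardinality


class Role(enum.Enum):
    """Role of an unrolled two-slice network node."""

    L1 = "layer1"  # demographic statics
    L2 = "layer2"  # onset statics
    L3 = "layer3"  # treatment statics
    PREV = "prev"  # dynamic variable at slice t-1
    CUR = "cur"  # dynamic variable at slice t
    TSO = "tso"  # cumulative time since onset (slice t)
    DEATH = "death"  # absorbing survival indicator (layer 6)


STATIC_ROLE_BY_LAYER = {1: Role.L1, 2: Role.L2, 3: Role.L3}

# Allowed parent roles per child role.  Edges into layer-1 statics, slice
# t-1 variables and TSO are never allowed (those nodes are inputs/evidence);
# intra-slice (CUR -> CUR) edges are allowed subject to acyclicity; the
# survival indicator may be influenced by everything except the
# contemporaneous slice (it is sampled before slice t during simulation).
_ALLOWED_PARENTS: dict[Role, frozenset[Role]] = {
    Role.L1: frozenset(),
    Role.L2: frozenset({Role.L1}),
    Role.L3: frozenset({Role.L1, Role.L2}),
    Role.PREV: frozenset(),
    Role.CUR: frozenset({Role.L1, Role.L2, Role.L3, Role.PREV, Role.TSO, Role.CUR}),
    Role.TSO: frozenset(),
    Role.DEATH: frozenset({Role.L1, Role.L2, Role.L3, Role.PREV, Role.TSO}),
}


@dataclass(frozen=True)
class NodeDef:
    """One node of the unrolled two-slice network."""

    name: str
    role: Role
    cardinality: int
    base: str = ""  # underlying variable name for PREV/CUR pairs

    def __post_init__(self) -> None:
        if self.cardinality < 2:
            raise ValueError(f"{self.name}: node cardinality must be >= 2")


class LayerMask:
    """Edge admissibility derived from the six-layer variable stratification."""

    def __init__(self, nodes: Sequence[NodeDef]):
        self.nodes = tuple(nodes)
        names = [n.name for n in nodes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate node names")
        self._role = {n.name: n.role for n in nodes}

    def allowed(self, parent: str, child: str) -> bool:
        if parent == child:
            return False
        return self._role[parent] in _ALLOWED_PARENTS[self._role[child]]

    def allowed_parent_roles(self, child_role: Role) -> frozenset[Role]:
        return _ALLOWED_PARENTS[child_role]

    def undirected_allowed(self, a: str, b: str) -> bool:
        """True if an edge between a and b is admissible in either direction."""
        return self.allowed(a, b) or self.allowed(b, a)


def prev_name(base: str) -> str:
    return f"{base}[t-1]"


def cur_name(base: str) -> str:
    return f"{base}[t]"


TSO_NODE = "tso"
DEATH_NODE = "death"


def unroll_nodes(
    specs: Sequence[VariableSpec],
    tso_cardinality: int = 3,
) -> list[NodeDef]:
    """Build the unrolled node set: statics, each dynamic at t-1 and t, TSO, death."""
    nodes: list[NodeDef] = []
    for s in specs:
        if s.kind == "static":
            nodes.append(NodeDef(s.name, STATIC_ROLE_BY_LAYER[s.layer], s.cardinality))
        else:
            nodes.append(NodeDef(prev_name(s.name), Role.PREV, s.cardinality, base=s.name))
            nodes.append(NodeDef(cur_name(s.name), Role.CUR, s.cardinality, base=s.name))
    nodes.append(NodeDef(TSO_NODE, Role.TSO, tso_cardinality, base=TSO_NODE))
    nodes.append(NodeDef(DEATH_NODE, Role.DEATH, 2, base=DEATH_NODE))
    return nodes


# ---------------------------------------------------------------------------
# YAML (de)serialization of variable specifications


def specs_to_dict(specs: Sequence[VariableSpec]) -> list[dict]:
    out = []
    for s in specs:
        q = s.quantization
        if isinstance(q, ClinicalThresholds):
            qd: dict = {"method": "clinical_thresholds", "cuts": list(q.cuts)}
        elif isinstance(q, Tertiles):
            qd = {"method": "tertiles"}
            if q.cuts is not None:
                qd["cuts"] = list(q.cuts)
        elif isinstance(q, Categorical):
            qd = {"method": "categorical", "labels": list(q.labels)}
        else:  # pragma: no cover
            raise TypeError(f"unknown quantization {type(q)}")
        out.append(
            {"name": s.name, "kind": s.kind, "layer": s.layer, "quantization": qd, "units": s.units}
        )
    return out


def specs_from_dict(items: Sequence[Mapping]) -> list[VariableSpec]:
    specs = []
    for it in items:
        qd = it["quantization"]
        method = qd["method"]
        if method == "clinical_thresholds":
            q: Quantization = ClinicalThresholds(tuple(float(c) for c in qd["cuts"]))
        elif method == "tertiles":
            cuts = qd.get("cuts")
            q = Tertiles(tuple(float(c) for c in cuts) if cuts else None)
        elif method == "categorical":
            q = Categorical(tuple(str(x) for x in qd["labels"]))
        else:
            raise ValueError(f"unknown quantization method {method!r}")
        specs.append(
            VariableSpec(
                name=str(it["name"]),
                kind=str(it["kind"]),
                layer=int(it["layer"]),
                quantization=q,
                units=str(it.get("units", "")),
            )
        )
    return specs
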