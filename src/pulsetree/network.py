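"""Arterial networks as labelled directed trees.

A :class:`Network` is a rooted tree of :class:`Vessel` segments.  Blood enters
at the root (ascending aorta); junction nodes have one or two children;
vessels with no children are *terminal* and carry a structured-tree outflow
boundary condition truncated at radius ``r_min_cm``.

The canonical 17-vessel aorta + head/neck topology used for single-ventricle
cohorts (DORV: native aorta; HLHS: surgically reconstructed aorta) is provided
by :func:`canonical_network` with cohort-mean dimensions.  Dimensions outside
an imaged region can be adapted to a patient's body weight by allometric
scaling (:func:`allometric_scale`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "Vessel",
    "Network",
    "AllometricReference",
    "NetworkValidationError",
    "allometric_scale",
    "build_network",
    "canonical_network",
    "CANONICAL_TERMINALS",
    "LARGE_GROUPS",
    "SMALL_GROUPS",
]

#: Stiffness-group membership of the canonical network (group -> vessel ids).
LARGE_GROUPS = {1: [1, 2, 3, 4, 7], 2: [10, 11, 14, 15], 3: [5, 12, 13], 4: [6, 8, 9, 16, 17]}
#: Small-vessel (structured-tree) groups; vessel 9 travels with its
#: contralateral pair 17; vessel 10 is non-terminal and its label is unused.
SMALL_GROUPS = {1: [7], 2: [10, 14, 15], 3: [12, 13], 4: [8, 9, 16, 17]}

CANONICAL_TERMINALS = frozenset({7, 8, 9, 12, 13, 14, 15, 16, 17})


class NetworkValidationError(ValueError):
    """Raised when a vessel table / edge list does not describe a valid tree."""


@dataclass(frozen=True)
class Vessel:
    """One large-vessel segment.

    Radii taper from ``r_in_cm`` at the proximal end to ``r_out_cm`` at the
    distal end; ``radius_at`` evaluates the taper.  ``r_min_cm`` (terminal
    vessels only) is the truncation radius of the attached structured tree.
    """

    id: int
    name: str
    length_cm: float
    r_in_cm: float
    r_out_cm: float
    group_large: int
    group_small: int | None = None
    terminal: bool = False
    r_min_cm: float | None = None

    def __post_init__(self):
        for f in ("length_cm", "r_in_cm", "r_out_cm"):
            if not getattr(self, f) > 0:
                raise ValueError(f"vessel {self.id}: {f} must be positive")
        if self.group_large not in (1, 2, 3, 4):
            raise ValueError(f"vessel {self.id}: group_large must be 1-4")
        if self.terminal:
            if self.r_min_cm is None or not (0 < self.r_min_cm < self.r_out_cm):
                raise ValueError(
                    f"vessel {self.id}: terminal vessel needs 0 < r_min_cm < r_out_cm"
                )
            if self.group_small not in (1, 2, 3, 4):
                raise ValueError(f"vessel {self.id}: terminal vessel needs group_small 1-4")

    def radius_at(self, x, taper: str = "exponential"):
        """Unstressed radius r0(x) for x in [0, L].

        The default exponential taper r_in*(r_out/r_in)^(x/L) is smooth,
        strictly positive and matches both measured end radii; a linear taper
        is available as a configuration alternative.
        """
        x = np.asarray(x, dtype=float)
        s = x / self.length_cm
        if taper == "exponential":
            return self.r_in_cm * (self.r_out_cm / self.r_in_cm) ** s
        if taper == "linear":
            return self.r_in_cm + (self.r_out_cm - self.r_in_cm) * s
        raise ValueError(f"unknown taper {taper!r}")


@dataclass(frozen=True)
class AllometricReference:
    """Literature dimension plus body weights for allometric scaling."""

    L1_cm: float
    W1_kg: float
    W2_kg: float
    exponent: float = 0.35

    def __post_init__(self):
        for f in ("L1_cm", "W1_kg", "W2_kg"):
            if not getattr(self, f) > 0:
                raise ValueError(f"AllometricReference.{f} must be positive")


def allometric_scale(ref: AllometricReference) -> float:
    """Scale a literature vessel dimension to a patient's body weight.

    L2 = L1 * (W1/W2)^exponent.  Applies identically to lengths and radii.
    """
    return ref.L1_cm * (ref.W1_kg / ref.W2_kg) ** ref.exponent


@dataclass(frozen=True)
class Network:
    """Rooted tree of vessels. ``children[id]`` lists the daughter ids."""

    vessels: dict = field(default_factory=dict)  # id -> Vessel
    children: dict = field(default_factory=dict)  # id -> tuple of ids
    root_id: int = 1

    @property
    def terminal_ids(self):
        return sorted(v.id for v in self.vessels.values() if v.terminal)

    def parent_of(self, vid: int) -> int | None:
        for p, kids in self.children.items():
            if vid in kids:
                return p
        return None

    def vessel(self, vid: int) -> Vessel:
        return self.vessels[vid]

    def __len__(self):
        return len(self.vessels)

    # -- serialization ----------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "root_id": self.root_id,
            "vessels": [asdict(self.vessels[k]) for k in sorted(self.vessels)],
            "edges": [[p, c] for p in sorted(self.children) for c in self.children[p]],
        }
        return json.dumps(payload, indent=1)

    @staticmethod
    def from_json(text: str) -> "Network":
        payload = json.loads(text)
        table = pd.DataFrame(payload["vessels"])
        return build_network(table, [tuple(e) for e in payload["edges"]])

    def to_csv(self, vessels_path, edges_path) -> None:
        rows = [asdict(self.vessels[k]) for k in sorted(self.vessels)]
        cols = ["id", "name", "length_cm", "r_in_cm", "r_out_cm",
                "group_large", "group_small", "terminal", "r_min_cm"]
        pd.DataFrame(rows)[cols].to_csv(vessels_path, index=False)
        edges = [[p, c] for p in sorted(self.children) for c in self.children[p]]
        pd.DataFrame(edges, columns=["parent", "child"]).to_csv(edges_path, index=False)

    @staticmethod
    def from_csv(vessels_path, edges_path) -> "Network":
        table = pd.read_csv(vessels_path)
        ed = pd.read_csv(edges_path)
        return build_network(table, list(zip(ed["parent"], ed["child"])))


def build_network(vessel_table, edge_list) -> Network:
    """Assemble and validate a Network from a vessel table and an edge list.

    ``vessel_table`` is a DataFrame (or list of dicts) with columns
    id, name, length_cm, r_in_cm, r_out_cm, group_large and optionally
    group_small, r_min_cm; ``edge_list`` is an iterable of (parent, child) id
    pairs.  Terminal flags are derived from the edge list.  Raises
    :class:`NetworkValidationError` on cycles, multiple parents, orphan
    vessels or duplicate ids.
    """
    table = pd.DataFrame(vessel_table)
    ids = [int(i) for i in table["id"]]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise NetworkValidationError(f"duplicate vessel ids: {dupes}")
    idset = set(ids)

    children: dict = {i: [] for i in ids}
    parent: dict = {}
    for p, c in edge_list:
        p, c = int(p), int(c)
        if p not in idset or c not in idset:
            raise NetworkValidationError(f"edge ({p},{c}) references unknown vessel id")
        if c in parent:
            raise NetworkValidationError(f"vessel {c} has multiple parents")
        parent[c] = p
        children[p].append(c)

    roots = [i for i in ids if i not in parent]
    if len(ids) > 1 and len(roots) != 1:
        raise NetworkValidationError(
            f"network must have exactly one root; found {sorted(roots)} "
            "(cycle or orphan vessels present)" if roots else
            "network has no root (cycle)"
        )
    root = roots[0] if roots else ids[0]

    # reachability from the root rules out cycles / disconnected parts
    seen, stack = set(), [root]
    while stack:
        v = stack.pop()
        if v in seen:
            raise NetworkValidationError(f"cycle detected at vessel {v}")
        seen.add(v)
        stack.extend(children[v])
    if seen != idset:
        raise NetworkValidationError(
            f"orphan vessels not reachable from root: {sorted(idset - seen)}"
        )
    for i in ids:
        if len(children[i]) > 2:
            raise NetworkValidationError(f"vessel {i} has more than two children")

    vessels = {}
    for _, row in table.iterrows():
        vid = int(row["id"])
        term = len(children[vid]) == 0
        gs = row.get("group_small")
        rm = row.get("r_min_cm")
        vessels[vid] = Vessel(
            id=vid,
            name=str(row.get("name", f"vessel {vid}")),
            length_cm=float(row["length_cm"]),
            r_in_cm=float(row["r_in_cm"]),
            r_out_cm=float(row["r_out_cm"]),
            group_large=int(row["group_large"]),
            group_small=None if gs is None or pd.isna(gs) else int(gs),
            terminal=term,
            r_min_cm=None if rm is None or pd.isna(rm) else float(rm),
        )
    return Network(vessels=vessels, children={i: tuple(children[i]) for i in ids}, root_id=root)


# -- canonical 17-vessel topology ----------------------------------------

# Cohort-mean dimensions (length, inlet radius, outlet radius), cm.
_CANONICAL_DIMS = {
    "DORV": {
        1: ("Asc aorta", 3.8, 1.18, 1.04),
        2: ("Aortic arch I", 1.6, 1.04, 1.00),
        3: ("Innominate", 4.3, 0.53, 0.53),
        4: ("Aortic arch II", 2.5, 1.00, 0.87),
        5: ("L common carotid", 20.1, 0.32, 0.31),
        6: ("L subclavian", 3.3, 0.36, 0.34),
        7: ("Desc aorta", 35.1, 0.87, 0.59),
        8: ("L brachial", 20.1, 0.31, 0.26),
        9: ("L vertebral", 14.3, 0.24, 0.23),
        10: ("R subclavian", 3.3, 0.36, 0.34),
        11: ("R common carotid", 17.1, 0.32, 0.30),
        12: ("L ext carotid", 17.1, 0.27, 0.24),
        13: ("L int carotid", 17.0, 0.21, 0.17),
        14: ("R int carotid", 17.0, 0.21, 0.17),
        15: ("R ext carotid", 17.1, 0.27, 0.24),
        16: ("R brachial", 20.1, 0.21, 0.21),
        17: ("R vertebral", 14.3, 0.24, 0.23),
    },
    "HLHS": {
        1: ("Asc aorta", 2.9, 1.36, 1.52),
        2: ("Aortic arch I", 1.5, 1.52, 1.31),
        3: ("Innominate", 3.1, 0.54, 0.54),
        4: ("Aortic arch II", 1.5, 1.31, 0.74),
        5: ("L common carotid", 20.1, 0.30, 0.27),
        6: ("L subclavian", 3.5, 0.21, 0.28),
        7: ("Desc aorta", 35.1, 0.74, 0.55),
        8: ("L brachial", 20.1, 0.30, 0.28),
        9: ("L vertebral", 14.3, 0.24, 0.22),
        10: ("R subclavian", 3.5, 0.21, 0.28),
        11: ("R common carotid", 17.1, 0.34, 0.31),
        12: ("L ext carotid", 17.1, 0.28, 0.26),
        13: ("L int carotid", 17.0, 0.24, 0.23),
        14: ("R int carotid", 17.0, 0.24, 0.23),
        15: ("R ext carotid", 17.1, 0.28, 0.26),
        16: ("R brachial", 20.1, 0.24, 0.23),
        17: ("R vertebral", 14.3, 0.24, 0.22),
    },
}

# Connectivity: ascending aorta feeds arch I + innominate; arch I feeds
# arch II + L common carotid; arch II feeds L subclavian + descending aorta;
# the innominate feeds the right subclavian + right common carotid; carotids
# split into internal/external branches, subclavians into brachial/vertebral.
_CANONICAL_EDGES = [
    (1, 2), (1, 3),
    (2, 4), (2, 5),
    (4, 6), (4, 7),
    (3, 10), (3, 11),
    (5, 12), (5, 13),
    (11, 14), (11, 15),
    (6, 8), (6, 9),
    (10, 16), (10, 17),
]


def _group_of(vid: int, groups: dict) -> int | None:
    for g, members in groups.items():
        if vid in members:
            return g
    return None


def canonical_network(cohort: str = "DORV") -> Network:
    """The canonical 17-vessel network with cohort-mean dimensions.

    Terminal vessels {7, 8, 9, 12, 13, 14, 15, 16, 17} carry structured-tree
    truncation radii of 0.001 cm (arteriolar level) except the descending
    aorta (vessel 7), terminated at 0.01 cm.
    """
    if cohort not in _CANONICAL_DIMS:
        raise ValueError(f"unknown cohort {cohort!r}; expected 'DORV' or 'HLHS'")
    rows = []
    for vid, (name, L, rin, rout) in _CANONICAL_DIMS[cohort].items():
        term = vid in CANONICAL_TERMINALS
        rows.append(
            dict(
                id=vid,
                name=name,
                length_cm=L,
                r_in_cm=rin,
                r_out_cm=rout,
                group_large=_group_of(vid, LARGE_GROUPS),
                group_small=_group_of(vid, SMALL_GROUPS),
                r_min_cm=(0.01 if vid == 7 else 0.001) if term else None,
            )
        )
    return build_network(pd.DataFrame(rows), _CANONICAL_EDGES)


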