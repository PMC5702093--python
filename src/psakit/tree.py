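"""Decision-tree specification and the Personal Support Algorithm classifier.

A :class:`TreeSpec` is an entirely data-driven tree: ordered split nodes with
integer cut points and terminal nodes carrying a group label.  Split semantics
are left-closed on the high side: with cuts ``[c1, c2, ...]`` a value ``v``
routes to child 0 when ``v < c1``, child ``j`` when ``c_j <= v < c_{j+1}``,
and to the last child when ``v >= c_last``.  The bundled reference tree
(``data/reference_tree.json``) encodes the published algorithm narrative with
documented, configurable cut points; derived trees produced by the growth
engine share the same schema and are directly classifiable.

Classification is a pure function of (record, tree version): the record's
scale profile plus its raw item codes (8 recoded to maximal dependence) are
routed from the root to exactly one terminal node.
"""

from __future__ import annotations

import json
from bisect import bisect_right
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache, total_ordering
from importlib import resources
from itertools import product
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .errors import ClassificationError, TreeSchemaError
from .records import AssessmentRecord, ScaleProfile, effective_code
from .scales import scale_profile

GROUP_DISPLAYS = ("1A", "1B", "1C", "2", "3", "4", "5", "6")

#: Declared domain (inclusive lo, hi) of every variable a tree may reference.
#: ADL items are expressed on the effective 0-6 scale (code 8 -> 6).
VARIABLE_RANGES: dict[str, tuple[int, int]] = {
    "self_reliance_impaired": (0, 1),
    "adl_short": (0, 16),
    "adl_hierarchy": (0, 6),
    "cps": (0, 6),
    "iadl_difficulty": (0, 6),
    "bathing": (0, 6),
    "personal_hygiene": (0, 6),
    "dressing_upper": (0, 6),
    "dressing_lower": (0, 6),
    "walking_indoors": (0, 6),
    "walking_outdoors": (0, 6),
    "locomotion": (0, 6),
    "toilet_use": (0, 6),
    "eating": (0, 6),
    "bed_mobility": (0, 6),
    "decision_making": (0, 4),
    "short_term_memory_ok": (0, 1),
    "making_self_understood": (0, 4),
    "bladder_incontinence": (0, 5),
    "bowel_incontinence": (0, 5),
    "unstable_conditions": (0, 1),
    "caregiver_distress": (0, 1),
    "living_alone": (0, 1),
    "on_waitlist_or_hold": (0, 1),
}

_ADL_CODE_ITEMS = frozenset(
    k for k in VARIABLE_RANGES
    if k in (
        "bathing", "personal_hygiene", "dressing_upper", "dressing_lower",
        "walking_indoors", "walking_outdoors", "locomotion", "toilet_use",
        "eating", "bed_mobility",
    )
)


@total_ordering
@dataclass(frozen=True)
class PsaGroup:
    """Ordered need group: top level 1-6, sublevels A/B/C only within group 1."""

    top_level: int
    sublevel: Optional[str] = None

    def __post_init__(self):
        if not 1 <= self.top_level <= 6:
            raise ValueError(f"top_level out of range: {self.top_level}")
        if self.sublevel is not None:
            if self.top_level != 1:
                raise ValueError("sublevels exist only for group 1")
            if self.sublevel not in ("A", "B", "C"):
                raise ValueError(f"invalid sublevel: {self.sublevel}")
        elif self.top_level == 1:
            raise ValueError("group 1 requires a sublevel (A, B, or C)")

    @property
    def display(self) -> str:
        return f"{self.top_level}{self.sublevel or ''}"

    @classmethod
    def from_display(cls, label: str) -> "PsaGroup":
        label = str(label).strip().upper()
        if label not in GROUP_DISPLAYS:
            raise ValueError(f"unknown group label: {label!r}")
        if label[0] == "1":
            return cls(1, label[1])
        return cls(int(label))

    def _key(self):
        return (self.top_level, self.sublevel or "")

    def __lt__(self, other: "PsaGroup"):
        return self._key() < other._key()


@dataclass(frozen=True)
class SplitNode:
    node_id: str
    variable: str
    cuts: tuple[int, ...]
    children: tuple[str, ...]


@dataclass(frozen=True)
class LeafNode:
    node_id: str
    group: Optional[str] = None
    n: Optional[int] = None
    mean: Optional[float] = None


@dataclass
class TreeSpec:
    """Validated, serialisable decision tree with a leaf-to-group mapping."""

    root_id: str
    nodes: dict[str, SplitNode | LeafNode]
    version: str = "unversioned"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    # -- structure ---------------------------------------------------------
    def validate(self) -> None:
        if self.root_id not in self.nodes:
            raise TreeSchemaError(f"root node {self.root_id!r} not defined")
        referenced: Counter[str] = Counter()
        known = set(VARIABLE_RANGES) | set(self.metadata.get("feature_ranges", ()))
        for node in self.nodes.values():
            if isinstance(node, SplitNode):
                if node.variable not in known:
                    raise TreeSchemaError(
                        f"node {node.node_id}: unknown variable {node.variable!r}"
                    )
                if list(node.cuts) != sorted(set(node.cuts)):
                    raise TreeSchemaError(
                        f"node {node.node_id}: cuts must be strictly increasing"
                    )
                if len(node.children) != len(node.cuts) + 1:
                    raise TreeSchemaError(
                        f"node {node.node_id}: expected {len(node.cuts) + 1} children"
                    )
                for child in node.children:
                    if child not in self.nodes:
                        raise TreeSchemaError(
                            f"node {node.node_id}: dangling child id {child!r}"
                        )
                    referenced[child] += 1
            elif node.group is not None and node.group not in GROUP_DISPLAYS and not str(node.group).isdigit():
                raise TreeSchemaError(
                    f"node {node.node_id}: invalid group label {node.group!r}"
                )
        if referenced.get(self.root_id):
            raise TreeSchemaError(f"cycle through root node {self.root_id!r}")
        multi = [k for k, c in referenced.items() if c > 1]
        if multi:
            raise TreeSchemaError(f"node {multi[0]!r} has multiple parents (not a tree)")
        # reachability + cycle check via DFS
        seen: set[str] = set()
        stack = [self.root_id]
        path: list[str] = []
        self._dfs(self.root_id, seen, path)
        unreachable = set(self.nodes) - seen
        if unreachable:
            raise TreeSchemaError(f"unreachable node {sorted(unreachable)[0]!r}")
        del stack

    def _dfs(self, nid: str, seen: set[str], path: list[str]) -> None:
        if nid in path:
            raise TreeSchemaError(f"cycle at node {nid!r}")
        if nid in seen:
            return
        seen.add(nid)
        node = self.nodes[nid]
        if isinstance(node, SplitNode):
            path.append(nid)
            for child in node.children:
                self._dfs(child, seen, path)
            path.pop()

    # -- convenience -------------------------------------------------------
    @property
    def leaves(self) -> list[LeafNode]:
        return [n for n in self.nodes.values() if isinstance(n, LeafNode)]

    @property
    def variables(self) -> list[str]:
        return sorted({n.variable for n in self.nodes.values() if isinstance(n, SplitNode)})

    def depth(self) -> int:
        def d(nid):
            node = self.nodes[nid]
            if isinstance(node, LeafNode):
                return 0
            return 1 + max(d(c) for c in node.children)

        return d(self.root_id)

    def route(self, features: Mapping[str, int]) -> str:
        """Terminal node id for a feature mapping."""
        nid = self.root_id
        while True:
            node = self.nodes[nid]
            if isinstance(node, LeafNode):
                return nid
            try:
                v = features[node.variable]
            except KeyError:
                raise ClassificationError(
                    f"missing classifier input: {node.variable}"
                ) from None
            if v is None:
                raise ClassificationError(f"missing classifier input: {node.variable}")
            nid = node.children[bisect_right(node.cuts, v)]

    def variable_range(self, var: str) -> tuple[float, float]:
        if var in VARIABLE_RANGES:
            return VARIABLE_RANGES[var]
        fr = self.metadata.get("feature_ranges", {})
        if var in fr:
            lo, hi = fr[var]
            return (lo, hi)
        raise TreeSchemaError(f"no declared range for variable {var!r}")

    def path_constraints(self, leaf_id: str) -> dict[str, tuple[int, int]]:
        """Variable -> inclusive (lo, hi) interval implied by the root-to-leaf path."""
        path = self._find_path(self.root_id, leaf_id)
        if path is None:
            raise TreeSchemaError(f"no such leaf: {leaf_id!r}")
        cons: dict[str, tuple[int, int]] = {}
        for nid, child_idx in path:
            node = self.nodes[nid]
            lo, hi = self.variable_range(node.variable)
            if child_idx > 0:
                lo = max(lo, node.cuts[child_idx - 1])
            if child_idx < len(node.cuts):
                hi = min(hi, node.cuts[child_idx] - 1)
            plo, phi = cons.get(node.variable, self.variable_range(node.variable))
            cons[node.variable] = (max(lo, plo), min(hi, phi))
        return cons

    def _find_path(self, nid, leaf_id, acc=()):
        if nid == leaf_id:
            return list(acc)
        node = self.nodes[nid]
        if isinstance(node, LeafNode):
            return None
        for i, child in enumerate(node.children):
            found = self._find_path(child, leaf_id, (*acc, (nid, i)))
            if found is not None:
                return found
        return None

    def leaves_for_group(self, display: str) -> list[str]:
        return [n.node_id for n in self.leaves if n.group == display]

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        nodes = []
        for node in self.nodes.values():
            if isinstance(node, SplitNode):
                nodes.append(
                    {
                        "id": node.node_id,
                        "variable": node.variable,
                        "cuts": list(node.cuts),
                        "children": list(node.children),
                    }
                )
            else:
                d: dict = {"id": node.node_id, "group": node.group}
                if node.n is not None:
                    d["n"] = node.n
                if node.mean is not None:
                    d["mean"] = node.mean
                nodes.append(d)
        return {
            "version": self.version,
            "metadata": self.metadata,
            "root": self.root_id,
            "nodes": nodes,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "TreeSpec":
        try:
            raw_nodes = payload["nodes"]
            root = payload["root"]
        except KeyError as exc:
            raise TreeSchemaError(f"tree JSON missing key: {exc}") from None
        nodes: dict[str, SplitNode | LeafNode] = {}
        for raw in raw_nodes:
            nid = raw.get("id")
            if nid is None:
                raise TreeSchemaError("node without id")
            if nid in nodes:
                raise TreeSchemaError(f"duplicate node id {nid!r}")
            if "variable" in raw:
                nodes[nid] = SplitNode(
                    node_id=nid,
                    variable=raw["variable"],
                    cuts=tuple(raw["cuts"]),
                    children=tuple(raw["children"]),
                )
            else:
                nodes[nid] = LeafNode(
                    node_id=nid,
                    group=raw.get("group"),
                    n=raw.get("n"),
                    mean=raw.get("mean"),
                )
        return cls(
            root_id=root,
            nodes=nodes,
            version=payload.get("version", "unversioned"),
            metadata=payload.get("metadata", {}),
        )


def load_tree(source) -> TreeSpec:
    """Load and validate a TreeSpec from a JSON path, handle, or string."""
    if hasattr(source, "read"):
        payload = json.load(source)
    else:
        text = str(source)
        if text.lstrip().startswith("{"):
            payload = json.loads(text)
        else:
            with open(source, encoding="utf-8") as fh:
                payload = json.load(fh)
    return TreeSpec.from_dict(payload)


def save_tree(tree: TreeSpec, dest) -> None:
    if hasattr(dest, "write"):
        json.dump(tree.to_dict(), dest, indent=1)
    else:
        with open(dest, "w", encoding="utf-8") as fh:
            json.dump(tree.to_dict(), fh, indent=1)


@lru_cache(maxsize=1)
def reference_tree() -> TreeSpec:
    """The bundled reference Personal Support Algorithm tree."""
    text = resources.files("psakit.data").joinpath("reference_tree.json").read_text()
    return load_tree(text)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def features_from(record: AssessmentRecord, profile: ScaleProfile) -> dict[str, int]:
    """Feature mapping a tree may route on: scale values plus effective codes."""
    feats = profile.as_features()
    for name, (lo, hi) in VARIABLE_RANGES.items():
        if name in feats:
            continue
        v = getattr(record, name, None)
        if v is None:
            continue
        feats[name] = effective_code(v) if name in _ADL_CODE_ITEMS else int(v)
    return feats


def classify(
    profile: ScaleProfile,
    record: AssessmentRecord,
    tree: TreeSpec | None = None,
) -> tuple[PsaGroup, str]:
    """Route one record to its PSA group; returns (group, terminal node id)."""
    tree = tree or reference_tree()
    leaf_id = tree.route(features_from(record, profile))
    leaf = tree.nodes[leaf_id]
    assert isinstance(leaf, LeafNode)
    if leaf.group is None:
        raise ClassificationError(f"terminal node {leaf_id!r} carries no group")
    return PsaGroup.from_display(leaf.group), leaf_id


def classify_cohort(
    records: Iterable[AssessmentRecord],
    tree: TreeSpec | None = None,
    policy: str = "reject",
) -> tuple[pd.DataFrame, pd.DataFrame, list[tuple[str, str]]]:
    """Classify every record; aggregate the group distribution.

    Returns ``(assignments, distribution, failures)`` where failures are
    (person_id, reason) pairs for unclassifiable records.  The distribution's
    ``percent`` column sums to 100 over classifiable records.
    """
    tree = tree or reference_tree()
    rows = []
    failures: list[tuple[str, str]] = []
    for rec in records:
        try:
            grp, leaf_id = classify(scale_profile(rec, policy), rec, tree)
        except Exception as exc:  # aggregated, not thrown
            failures.append((rec.person_id, str(exc)))
            continue
        rows.append(
            {
                "person_id": rec.person_id,
                "top_level": grp.top_level,
                "display": grp.display,
                "terminal_node_id": leaf_id,
                "tree_version": tree.version,
            }
        )
    assignments = pd.DataFrame(
        rows, columns=["person_id", "top_level", "display", "terminal_node_id", "tree_version"]
    )
    if len(assignments):
        counts = assignments["display"].value_counts().sort_index()
        distribution = pd.DataFrame(
            {"n": counts, "percent": 100.0 * counts / counts.sum()}
        ).rename_axis("display").reset_index()
    else:
        distribution = pd.DataFrame(columns=["display", "n", "percent"])
    return assignments, distribution, failures


# ---------------------------------------------------------------------------
# discretised-domain sweep
# ---------------------------------------------------------------------------

def sweep_values(tree: TreeSpec) -> dict[str, list[int]]:
    """Representative values per tree variable, exhaustive w.r.t. the cuts.

    For each variable the cut points partition its declared range into
    equivalence classes the tree cannot distinguish further; the class lower
    bounds (range minimum plus each in-range cut) therefore cover the full
    domain exactly.
    """
    cuts: dict[str, set[int]] = {}
    for node in tree.nodes.values():
        if isinstance(node, SplitNode):
            cuts.setdefault(node.variable, set()).update(node.cuts)
    out = {}
    for var, cs in sorted(cuts.items()):
        lo, hi = tree.variable_range(var)
        vals = {lo} | {c for c in cs if lo <= c <= hi}
        out[var] = sorted(vals)
    return out


def sweep_classify(tree: TreeSpec | None = None) -> Counter:
    """Classify the full discretised input domain; returns label counts.

    Every combination of representative variable values is routed through the
    tree, so the returned counter's key set is exactly the set of reachable
    group labels.
    """
    tree = tree or reference_tree()
    grid = sweep_values(tree)
    variables = list(grid)
    counts: Counter[str] = Counter()
    for combo in product(*(grid[v] for v in variables)):
        feats = dict(zip(variables, combo))
        leaf = tree.nodes[tree.route(feats)]
        counts[leaf.group] += 1
    return counts
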