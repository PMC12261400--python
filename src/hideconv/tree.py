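"""Cell-type hierarchies.

A cell hierarchy is a forest of uniquely named nodes: the roots are the
coarsest populations (e.g. the nine major breast cell types), the leaves are
the finest annotated cell types.  A *level* is an antichain of nodes that
covers every leaf exactly once — when a population is not subdivided at some
resolution, the node itself stands at that level, so levels can repeat node
names across resolutions without introducing phantom nodes.

Trees are read from a nested JSON document::

    {
      "tree":   [{"name": "T cell", "children": [{"name": "CD4 T cell"}, ...]}, ...],
      "levels": [{"name": "major", "nodes": ["T cell", ...]}, ...]
    }

``levels`` is optional; :meth:`CellTree.default_levels` derives one level per
depth with the stand-in convention above.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CellTree",
    "TreeError",
    "parse_tree",
    "load_tree",
    "breast_tree",
    "tree_to_document",
    "aggregate_proportions",
]


class TreeError(ValueError):
    """Raised for malformed hierarchy documents or invalid level queries."""


@dataclass(frozen=True)
class CellTree:
    """Immutable cell-type tree (possibly a forest).

    Attributes
    ----------
    children_of
        Node name -> ordered child names (document order). Leaves map to ().
    parent_of
        Node name -> parent name, or ``None`` for roots.
    roots
        Root names in document order.
    levels
        Declared named levels (name -> ordered node names). May be empty.
    """

    children_of: Mapping[str, tuple[str, ...]]
    parent_of: Mapping[str, str | None]
    roots: tuple[str, ...]
    levels: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    # -- basic queries ---------------------------------------------------
    @property
    def nodes(self) -> tuple[str, ...]:
        """All node names in pre-order."""
        out: list[str] = []

        def walk(name: str) -> None:
            out.append(name)
            for child in self.children_of[name]:
                walk(child)

        for r in self.roots:
            walk(r)
        return tuple(out)

    @property
    def leaves(self) -> tuple[str, ...]:
        return tuple(n for n in self.nodes if not self.children_of[n])

    def is_leaf(self, name: str) -> bool:
        self._check_node(name)
        return not self.children_of[name]

    def leaf_descendants(self, name: str) -> tuple[str, ...]:
        """Leaves below (or equal to) ``name``, in pre-order."""
        self._check_node(name)
        if not self.children_of[name]:
            return (name,)
        out: list[str] = []
        for child in self.children_of[name]:
            out.extend(self.leaf_descendants(child))
        return tuple(out)

    def is_ancestor_or_self(self, ancestor: str, node: str) -> bool:
        self._check_node(ancestor)
        cur: str | None = node
        while cur is not None:
            if cur == ancestor:
                return True
            cur = self.parent_of[cur]
        return False

    def _check_node(self, name: str) -> None:
        if name not in self.children_of:
            raise TreeError(f"unknown node: {name!r}")

    # -- levels ----------------------------------------------------------
    def level(self, level: str | Sequence[str]) -> tuple[str, ...]:
        """Resolve a level by declared name or explicit node list and validate it."""
        if isinstance(level, str):
            if level not in self.levels:
                raise TreeError(f"undeclared level: {level!r}")
            nodes = tuple(self.levels[level])
        else:
            nodes = tuple(level)
        self.validate_level(nodes)
        return nodes

    def validate_level(self, nodes: Sequence[str]) -> None:
        """A valid level is an antichain covering every leaf exactly once."""
        for n in nodes:
            self._check_node(n)
        if len(set(nodes)) != len(nodes):
            dup = next(n for n in nodes if list(nodes).count(n) > 1)
            raise TreeError(f"level repeats node {dup!r}")
        for leaf in self.leaves:
            covering = [n for n in nodes if self.is_ancestor_or_self(n, leaf)]
            if len(covering) != 1:
                raise TreeError(
                    f"leaf {leaf!r} is covered by {len(covering)} level nodes "
                    f"({covering!r}); a level must cover each leaf exactly once"
                )

    def default_levels(self) -> list[tuple[str, tuple[str, ...]]]:
        """One level per depth, repeating unsubdivided nodes downwards."""
        out: list[tuple[str, tuple[str, ...]]] = []
        current = self.roots
        depth = 0
        while True:
            out.append((f"level_{depth}", current))
            nxt: list[str] = []
            for n in current:
                kids = self.children_of[n]
                nxt.extend(kids if kids else (n,))
            if tuple(nxt) == current:
                break
            current = tuple(nxt)
            depth += 1
        return out

    def ordered_levels(
        self, levels: Sequence[str | Sequence[str]] | None = None
    ) -> list[tuple[str, tuple[str, ...]]]:
        """Resolve the coarse-to-fine level sequence used by the deconvolution.

        ``None`` uses the declared levels (document order) when present,
        otherwise the depth-derived default.
        """
        if levels is None:
            if self.levels:
                return [(name, self.level(name)) for name in self.levels]
            return self.default_levels()
        out = []
        for i, lv in enumerate(levels):
            name = lv if isinstance(lv, str) else f"level_{i}"
            out.append((name, self.level(lv)))
        return out


# -- parsing -------------------------------------------------------------

def parse_tree(document: Mapping | Sequence) -> CellTree:
    """Parse a nested hierarchy document into a :class:`CellTree`.

    Accepts the full ``{"tree": [...], "levels": [...]}`` form, a bare list
    of root nodes, or a single root node object.
    """
    if isinstance(document, Mapping):
        if "tree" in document:
            forest = document["tree"]
            levels_doc = document.get("levels", [])
        elif "name" in document:
            forest, levels_doc = [document], []
        else:
            raise TreeError("document has neither a 'tree' entry nor a 'name'")
    else:
        forest, levels_doc = list(document), []
    if not forest:
        raise TreeError("empty tree")

    children_of: dict[str, tuple[str, ...]] = {}
    parent_of: dict[str, str | None] = {}

    def add(node: Mapping, parent: str | None) -> str:
        if not isinstance(node, Mapping) or "name" not in node:
            raise TreeError(f"node without a 'name': {node!r}")
        name = node["name"]
        if not isinstance(name, str) or not name:
            raise TreeError(f"invalid node name: {name!r}")
        if name in parent_of:
            # Shared/self-referencing subtrees surface here as revisits.
            raise TreeError(f"duplicate node name: {name!r}")
        parent_of[name] = parent
        children_of[name] = ()
        kids = node.get("children") or []
        children_of[name] = tuple(add(child, name) for child in kids)
        return name

    roots = tuple(add(node, None) for node in forest)

    levels: dict[str, tuple[str, ...]] = {}
    if isinstance(levels_doc, Mapping):
        levels_doc = [{"name": k, "nodes": v} for k, v in levels_doc.items()]
    for entry in levels_doc:
        levels[entry["name"]] = tuple(entry["nodes"])

    tree = CellTree(children_of, parent_of, roots, levels)
    for name in levels:
        tree.validate_level(levels[name])
    return tree


def load_tree(path: str | Path) -> CellTree:
    with open(path, encoding="utf-8") as fh:
        return parse_tree(json.load(fh))


def breast_tree() -> CellTree:
    """The packaged breast-cancer hierarchy (9 major / 13 minor / 34 leaf types)."""
    doc = resources.files("hideconv.data").joinpath("breast_tree.json").read_text("utf-8")
    return parse_tree(json.loads(doc))


def tree_to_document(tree: CellTree) -> dict:
    """Inverse of :func:`parse_tree` (levels included)."""

    def node_doc(name: str) -> dict:
        kids = tree.children_of[name]
        doc: dict = {"name": name}
        if kids:
            doc["children"] = [node_doc(c) for c in kids]
        return doc

    return {
        "tree": [node_doc(r) for r in tree.roots],
        "levels": [{"name": k, "nodes": list(v)} for k, v in tree.levels.items()],
    }


# -- aggregation ---------------------------------------------------------

def aggregate_proportions(
    C_leaf: pd.DataFrame, tree: CellTree, level: str | Sequence[str]
) -> pd.DataFrame:
    """Sum leaf-level proportions up to a coarser level.

    Parameters
    ----------
    C_leaf
        Proportions, leaves x samples; its index must be exactly the tree's
        leaf set.
    level
        Declared level name or explicit antichain.

    Returns
    -------
    Proportions, level nodes x samples. Column sums are preserved because a
    level covers each leaf exactly once.
    """
    nodes = tree.level(level)
    leaf_set = set(tree.leaves)
    missing = [l for l in C_leaf.index if l not in leaf_set]
    if missing:
        raise TreeError(f"rows are not tree leaves: {missing!r}")
    absent = leaf_set - set(C_leaf.index)
    if absent:
        raise TreeError(f"leaves missing from the proportion matrix: {sorted(absent)!r}")

    member = np.zeros((len(nodes), C_leaf.shape[0]))
    leaf_pos = {l: i for i, l in enumerate(C_leaf.index)}
    for r, node in enumerate(nodes):
        for leaf in tree.leaf_descendants(node):
            member[r, leaf_pos[leaf]] = 1.0
    values = member @ C_leaf.to_numpy(dtype=float)
    return pd.DataFrame(values, index=list(nodes), columns=C_leaf.columns)
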