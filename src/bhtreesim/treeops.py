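"""Tree assembly, pruning, incomplete sampling, statistics and Newick I/O.

Lineage records from the event loop are assembled into a rooted binary
tree with a stem edge.  Node times are measured from the origin of the
stem; edge lengths are inter-event times.  Extant tips are labelled
``t1, t2, ...`` and extinct tips ``x1, x2, ...``.  Per-node shift
annotations (scaling factors and 0/1 shift flags) ride along through
pruning and sampling and can be exported as a sidecar TSV or embedded as
NHX comments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .engine import (
    COMPLETED,
    EXTINCT_STATUS,
    SINGLE_SURVIVOR,
    TERMINATED,
    Lineage,
)
from .errors import (
    DuplicateLabelError,
    NewickParseError,
    SamplingError,
    TreeStructureError,
)
from .timespec import RandomStream

__all__ = [
    "Node",
    "PhyloTree",
    "TreeStats",
    "PruneResult",
    "ShiftReport",
    "assemble_tree",
    "prune_extinct",
    "sample_tips",
    "tree_stats",
    "write_newick",
    "read_newick",
    "shift_report",
    "write_annotations",
]


@dataclass
class Node:
    id: int
    parent: int | None
    length: float
    time: float
    label: str | None = None
    is_tip: bool = False
    extant: bool = False
    sp_factor: float = 1.0
    ext_factor: float = 1.0
    sp_shifted: bool = False
    ext_shifted: bool = False
    children: list[int] = field(default_factory=list)

    def copy(self) -> "Node":
        n = Node(**{k: getattr(self, k) for k in (
            "id", "parent", "length", "time", "label", "is_tip", "extant",
            "sp_factor", "ext_factor", "sp_shifted", "ext_shifted")})
        n.children = list(self.children)
        return n


class PhyloTree:
    """Rooted tree with a stem edge and per-node annotations.

    The root's own ``length`` is always 0; the edge subtending the root is
    held in ``stem_length``.
    """

    def __init__(self, nodes: dict[int, Node], root: int, stem_length: float):
        self.nodes = nodes
        self.root = root
        self.stem_length = stem_length

    # -- structure helpers -------------------------------------------------

    def tip_nodes(self) -> list[Node]:
        return [n for n in self.nodes.values() if n.is_tip]

    def extant_tip_nodes(self) -> list[Node]:
        return [n for n in self.nodes.values() if n.is_tip and n.extant]

    @property
    def n_tips(self) -> int:
        return sum(1 for n in self.nodes.values() if n.is_tip)

    @property
    def n_extant_tips(self) -> int:
        return sum(1 for n in self.nodes.values() if n.is_tip and n.extant)

    def postorder(self) -> Iterator[Node]:
        stack: list[tuple[int, bool]] = [(self.root, False)]
        while stack:
            nid, expanded = stack.pop()
            node = self.nodes[nid]
            if expanded or not node.children:
                yield node
            else:
                stack.append((nid, True))
                for c in reversed(node.children):
                    stack.append((c, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = self.nodes[stack.pop()]
            yield node
            stack.extend(reversed(node.children))

    def copy(self) -> "PhyloTree":
        return PhyloTree(
            {nid: n.copy() for nid, n in self.nodes.items()}, self.root, self.stem_length
        )

    def validate(self, rel_tol: float = 1e-9) -> None:
        """Check connectivity, parent/child symmetry and time additivity."""
        root = self.nodes[self.root]
        if root.parent is not None:
            raise TreeStructureError("root has a parent")
        if root.length != 0.0:
            raise TreeStructureError("root length must be 0 (stem held separately)")
        seen = set()
        for node in self.preorder():
            if node.id in seen:
                raise TreeStructureError("cycle detected")
            seen.add(node.id)
            expected = (
                self.stem_length if node.parent is None
                else self.nodes[node.parent].time + node.length
            )
            if not math.isclose(node.time, expected, rel_tol=rel_tol, abs_tol=1e-12):
                raise TreeStructureError(
                    f"node {node.id} time {node.time} inconsistent with path sum {expected}"
                )
            for c in node.children:
                if self.nodes[c].parent != node.id:
                    raise TreeStructureError("parent/child pointers disagree")
        if seen != set(self.nodes):
            raise TreeStructureError("unreachable nodes present")

    def is_ultrametric(self, rel_tol: float = 1e-9) -> bool:
        times = [n.time for n in self.tip_nodes()]
        ref = max(times)
        return all(math.isclose(t, ref, rel_tol=rel_tol, abs_tol=1e-12) for t in times)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<PhyloTree {self.n_tips} tips ({self.n_extant_tips} extant), "
            f"stem={self.stem_length:g}>"
        )


# ---------------------------------------------------------------------------
# assembly from lineage records


def assemble_tree(lineages: Sequence[Lineage], horizon: float) -> PhyloTree:
    """Assemble truncated lineage records into a :class:`PhyloTree`.

    Under symmetric speciation each terminated mother maps to one internal
    node whose children are her two descendants; under budding each of a
    mother's speciation events maps to an internal node with the mother
    continuing along one child edge.  Lineages with open end times become
    extant tips at ``horizon``.
    """
    by_id = {lin.id: lin for lin in lineages}
    roots = [lin for lin in lineages if lin.parent_id is None]
    if len(roots) != 1:
        raise TreeStructureError(f"expected exactly one origin lineage, got {len(roots)}")
    origin = roots[0]
    for lin in lineages:
        if lin.parent_id is not None and lin.parent_id not in by_id:
            raise TreeStructureError(f"lineage {lin.id} references missing parent")

    nodes: dict[int, Node] = {}
    next_id = 0

    def new_node(parent: int | None, time: float, length: float, lin: Lineage,
                 is_tip: bool, extant: bool) -> Node:
        nonlocal next_id
        if length < 0:
            raise TreeStructureError(f"negative edge length at lineage {lin.id}")
        node = Node(
            id=next_id, parent=parent, length=length, time=time,
            is_tip=is_tip, extant=extant,
            sp_factor=lin.sp_factor, ext_factor=lin.ext_factor,
            sp_shifted=lin.sp_shifted, ext_shifted=lin.ext_shifted,
        )
        nodes[next_id] = node
        if parent is not None:
            nodes[parent].children.append(node.id)
        next_id += 1
        return node

    # (lineage id, parent node id, segment start time)
    stack: list[tuple[int, int | None, float]] = [(origin.id, None, origin.origin_time)]
    while stack:
        lid, parent_node, start = stack.pop()
        lin = by_id[lid]
        end = lin.end_time if lin.end_time is not None else horizon
        if end < start:
            raise TreeStructureError(f"lineage {lid} ends before it starts")
        if lin.fate == TERMINATED:
            if len(lin.children) != 2 or any(ct != end for _, ct in lin.children):
                raise TreeStructureError(
                    f"terminated lineage {lid} must have two children at its end time"
                )
            node = new_node(parent_node, end, end - start, lin, False, False)
            for cid, ct in lin.children:
                stack.append((cid, node.id, ct))
        else:
            cur_parent, cur_start = parent_node, start
            for cid, ct in lin.children:
                if ct < cur_start or ct > end:
                    raise TreeStructureError(
                        f"child of lineage {lid} born outside its lifespan"
                    )
                node = new_node(cur_parent, ct, ct - cur_start, lin, False, False)
                stack.append((cid, node.id, ct))
                cur_parent, cur_start = node.id, ct
            new_node(cur_parent, end, end - cur_start, lin,
                     True, lin.end_time is None)

    root = nodes[0]
    stem_length = root.length
    root.length = 0.0
    tree = PhyloTree(nodes, root.id, stem_length)
    _relabel_tips(tree)
    return tree


def _relabel_tips(tree: PhyloTree) -> None:
    n_extant = n_extinct = 0
    for node in tree.preorder():
        if not node.is_tip:
            node.label = None
            continue
        if node.extant:
            n_extant += 1
            node.label = f"t{n_extant}"
        else:
            n_extinct += 1
            node.label = f"x{n_extinct}"


# ---------------------------------------------------------------------------
# pruning and sampling


@dataclass
class PruneResult:
    status: str
    tree: PhyloTree | None


def _retain_tips(tree: PhyloTree, keep_ids: set[int]) -> PhyloTree:
    """Subtree spanned by the kept tips, with degree-2 nodes suppressed.

    Edge lengths of suppressed nodes are summed exactly; removed basal
    history is absorbed into the stem length.
    """
    t = tree.copy()
    needed: set[int] = set()
    for tid in keep_ids:
        nid = tid
        while nid is not None and nid not in needed:
            needed.add(nid)
            nid = t.nodes[nid].parent
    for nid in list(t.nodes):
        if nid in needed:
            t.nodes[nid].children = [c for c in t.nodes[nid].children if c in needed]
        else:
            del t.nodes[nid]
    # suppress internal degree-2 nodes (never a kept tip)
    for nid in list(t.nodes):
        node = t.nodes.get(nid)
        if node is None or node.is_tip or nid == t.root:
            continue
        if len(node.children) == 1:
            child = t.nodes[node.children[0]]
            child.parent = node.parent
            child.length += node.length
            parent = t.nodes[node.parent]
            parent.children[parent.children.index(nid)] = child.id
            del t.nodes[nid]
    # absorb a unary chain above the new root into the stem
    while not t.nodes[t.root].is_tip and len(t.nodes[t.root].children) == 1:
        old = t.nodes.pop(t.root)
        child = t.nodes[old.children[0]]
        child.parent = None
        t.stem_length += child.length
        child.length = 0.0
        t.root = child.id
    return t


def prune_extinct(tree: PhyloTree) -> PruneResult:
    """Remove all lineages without extant descendants.

    Returns status ``extinct`` (no tree) if nothing survives,
    ``single_survivor`` (no tree) for exactly one extant tip, otherwise
    ``completed`` with the reconstructed, ultrametric tree.
    """
    extant = [n.id for n in tree.extant_tip_nodes()]
    if len(extant) == 0:
        return PruneResult(EXTINCT_STATUS, None)
    if len(extant) == 1:
        return PruneResult(SINGLE_SURVIVOR, None)
    return PruneResult(COMPLETED, _retain_tips(tree, set(extant)))


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def sample_tips(
    tree: PhyloTree, frac: float, method: str, stream: RandomStream
) -> PhyloTree:
    """Incomplete species sampling on a reconstructed (all-extant) tree.

    Retains ``round(N * frac)`` tips chosen uniformly at random without
    replacement (``method="uniform"``) or by successive draws with
    probability proportional to the current pendant branch lengths
    (``method="proportional"``: longer branches are more likely sampled).
    """
    if not (0.0 < frac <= 1.0):
        raise SamplingError(f"frac must be in (0, 1], got {frac!r}")
    tips = tree.tip_nodes()
    if any(not n.extant for n in tips):
        raise SamplingError("sample_tips requires a tree pruned to extant tips")
    if frac == 1.0:
        return tree.copy()
    n_keep = _round_half_up(len(tips) * frac)
    if n_keep < 2:
        raise SamplingError(
            f"round({len(tips)} * {frac}) = {n_keep} tips; at least 2 required"
        )
    rng = stream.gen
    if method == "uniform":
        chosen_idx = rng.choice(len(tips), size=n_keep, replace=False)
        keep = {tips[i].id for i in chosen_idx}
    elif method == "proportional":
        weights = [t.length for t in tips]
        if sum(weights) <= 0:
            raise SamplingError("all pendant branch lengths are zero")
        pool = list(range(len(tips)))
        keep = set()
        for _ in range(n_keep):
            total = sum(weights[i] for i in pool)
            u = rng.uniform(0.0, total)
            for j, i in enumerate(pool):
                if u < weights[i]:
                    keep.add(tips[i].id)
                    pool.pop(j)
                    break
                u -= weights[i]
            else:  # float round-off
                keep.add(tips[pool[-1]].id)
                pool.pop()
    else:
        raise SamplingError(f"unknown sampling method {method!r}")
    return _retain_tips(tree, keep)


# ---------------------------------------------------------------------------
# statistics


@dataclass
class TreeStats:
    extant_tips: int
    total_tips: int
    stem_age: float
    oldest_branching_time: float | None
    total_branch_length: float
    ltt: list[tuple[float, int]]


def tree_stats(tree: PhyloTree) -> TreeStats:
    """Summary statistics of a tree.

    ``oldest_branching_time`` is the time of the earliest internal node
    measured from the origin of the stem (None for a one-tip tree);
    ``total_branch_length`` includes the stem edge; ``ltt`` is the
    lineages-through-time step function as (time, count) breakpoints.
    """
    internal_times = [n.time for n in tree.nodes.values() if not n.is_tip]
    tips = tree.tip_nodes()
    deltas: dict[float, int] = {0.0: 1}
    for node in tree.nodes.values():
        if not node.is_tip:
            d = len(node.children) - 1
            if d:
                deltas[node.time] = deltas.get(node.time, 0) + d
        elif not node.extant:
            deltas[node.time] = deltas.get(node.time, 0) - 1
    ltt = []
    c = 0
    for t in sorted(deltas):
        c += deltas[t]
        ltt.append((t, c))
    return TreeStats(
        extant_tips=tree.n_extant_tips,
        total_tips=tree.n_tips,
        stem_age=max(n.time for n in tips),
        oldest_branching_time=min(internal_times) if internal_times else None,
        total_branch_length=tree.stem_length
        + sum(n.length for n in tree.nodes.values()),
        ltt=ltt,
    )


# ---------------------------------------------------------------------------
# Newick I/O


def _fmt_len(x: float) -> str:
    return f"{x:.12g}"


def _nhx(node: Node) -> str:
    return (
        f"[&&NHX:sp_factor={_fmt_len(node.sp_factor)}"
        f":ext_factor={_fmt_len(node.ext_factor)}"
        f":sp_shifted={int(node.sp_shifted)}"
        f":ext_shifted={int(node.ext_shifted)}"
        f":extant={int(node.extant)}]"
    )


def write_newick(tree: PhyloTree, annotations: bool = False) -> str:
    """Serialize to Newick with branch lengths and a trailing root (stem) edge.

    With ``annotations=True``, shift annotations are embedded as NHX
    comments; by default the Newick stays consumable by any standard parser
    and annotations go to the sidecar table (:func:`write_annotations`).
    """
    parts: dict[int, str] = {}
    for node in tree.postorder():
        suffix = _nhx(node) if annotations else ""
        if node.is_tip and not node.children:
            parts[node.id] = f"{node.label}:{_fmt_len(node.length)}{suffix}"
        else:
            inner = ",".join(parts.pop(c) for c in node.children)
            if node.id == tree.root:
                parts[node.id] = f"({inner}){node.label or ''}"
            else:
                parts[node.id] = (
                    f"({inner}){node.label or ''}:{_fmt_len(node.length)}{suffix}"
                )
    root = tree.nodes[tree.root]
    body = parts.pop(tree.root)
    if root.is_tip and not root.children:
        body = f"({body})"
    return f"{body}:{_fmt_len(tree.stem_length)};"


def read_newick(text: str) -> PhyloTree:
    """Parse a Newick string (delegating syntax to dendropy).

    The trailing root edge length becomes the stem; a unary root (as
    produced by :func:`write_newick` for one-tip trees) is collapsed.  Tips
    whose labels start with ``x`` are marked extinct, matching the writer's
    labelling convention.
    """
    import dendropy

    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,  # duplicate labels checked below
            preserve_underscores=True,
        )
    except Exception as exc:
        raise NewickParseError(f"invalid Newick: {exc}") from exc

    nodes: dict[int, Node] = {}
    next_id = 0
    seen_labels: set[str] = set()

    def convert(dnode, parent_id: int | None, parent_time: float) -> int:
        nonlocal next_id
        length = dnode.edge.length if dnode.edge.length is not None else 0.0
        if parent_id is None:
            length = 0.0
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        is_tip = dnode.is_leaf()
        if is_tip:
            if label in seen_labels:
                raise DuplicateLabelError(f"duplicate tip label {label!r}")
            if label is not None:
                seen_labels.add(label)
        node = Node(
            id=next_id, parent=parent_id, length=length,
            time=parent_time + length, label=label,
            is_tip=is_tip,
            extant=is_tip and not (label or "").startswith("x"),
        )
        nodes[next_id] = node
        if parent_id is not None:
            nodes[parent_id].children.append(node.id)
        next_id += 1
        my_id = node.id
        for child in dnode.child_nodes():
            convert(child, my_id, node.time)
        return my_id

    seed = dtree.seed_node
    stem = seed.edge.length if seed.edge.length is not None else 0.0
    children = seed.child_nodes()
    if len(children) == 1 and children[0].is_leaf():
        # unary root wrapper, e.g. "(t1:0):3;" for a one-tip tree; any
        # child edge length is folded into the stem so root.length stays 0
        edge = children[0].edge.length if children[0].edge.length is not None else 0.0
        stem += edge
        root_id = convert(children[0], None, stem)
    else:
        root_id = convert(seed, None, stem)
    return PhyloTree(nodes, root_id, stem)


# ---------------------------------------------------------------------------
# shift annotations


@dataclass
class ShiftReport:
    """Per-node shift annotations plus 0/1 tip indicator vectors."""

    table: pd.DataFrame
    shifted_sp_living: pd.Series
    shifted_sp_extinct: pd.Series
    shifted_ext_living: pd.Series
    shifted_ext_extinct: pd.Series

    def vectors(self) -> dict[str, pd.Series]:
        return {
            "shifted.sp.living": self.shifted_sp_living,
            "shifted.sp.extinct": self.shifted_sp_extinct,
            "shifted.ext.living": self.shifted_ext_living,
            "shifted.ext.extinct": self.shifted_ext_extinct,
        }


def _node_label(node: Node) -> str:
    return node.label if node.label else f"node{node.id}"


def shift_report(tree: PhyloTree) -> ShiftReport:
    """Tabulate per-node scaling factors and shift flags."""
    rows = []
    for node in tree.preorder():
        rows.append(
            dict(
                node_label=_node_label(node),
                node_id=node.id,
                sp_factor=node.sp_factor,
                ext_factor=node.ext_factor,
                sp_shifted=int(node.sp_shifted),
                ext_shifted=int(node.ext_shifted),
                is_tip=node.is_tip,
                extant=node.extant,
            )
        )
    table = pd.DataFrame(rows)

    def vec(extant: bool, col: str) -> pd.Series:
        tips = table[table.is_tip & (table.extant == extant)]
        return pd.Series(tips[col].values, index=tips.node_label.values, dtype=int)

    return ShiftReport(
        table=table,
        shifted_sp_living=vec(True, "sp_shifted"),
        shifted_sp_extinct=vec(False, "sp_shifted"),
        shifted_ext_living=vec(True, "ext_shifted"),
        shifted_ext_extinct=vec(False, "ext_shifted"),
    )


def write_annotations(trees: "PhyloTree | Iterable[PhyloTree]", path: str) -> None:
    """Sidecar TSV of per-node annotations for one tree or a batch."""
    if isinstance(trees, PhyloTree):
        trees = [trees]
    frames = []
    for i, tree in enumerate(trees):
        tbl = shift_report(tree).table.copy()
        tbl.insert(0, "tree", i)
        frames.append(tbl)
    out = pd.concat(frames, ignore_index=True)
    out = out[["tree", "node_label", "sp_factor", "ext_factor",
               "sp_shifted", "ext_shifted", "extant"]]
    out.to_csv(path, sep="\t", index=False)
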