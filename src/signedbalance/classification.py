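"""Reduce corner sign matrices to unlabeled graphs of node classes.

Two actors belong to the same class when they are structurally
interchangeable: they hold the same sign towards every class and every
class holds the same sign towards them, and the classes partition is
*equitable* -- all members of a class have the same number of liked /
liking neighbours in every class.  A converged state is then summarised
by a small signed digraph between classes (a :class:`ClassGraph`) plus
the class sizes, which is what gets tallied over an ensemble.

The refinement starts from the per-node counts M(i) (liked others,
``s[i, m] = +1``) and L(i) (likers, ``s[l, i] = +1``) and iterates
signed neighbourhood-profile splitting to a fixed point, which yields
the coarsest equitable partition.  Blocks that still mix signs (possible
only for exotic states, e.g. the two-clique balanced state where every
node has identical counts) are split further -- first along connected
components of the positive subgraph, as a last resort into singletons --
and the refinement is re-run until every block is sign-uniform.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from math import factorial
from pathlib import Path

import numpy as np
from scipy.sparse.csgraph import connected_components

from .signed_network import (
    SignMatrix,
    TemplateSpec,
    TEMPLATE_KINDS,
    TEMPLATE_PATTERNS,
)

__all__ = [
    "Partition",
    "ClassGraph",
    "InconsistentPartitionError",
    "refine_classes",
    "class_graph",
    "canonical_key",
    "canonical_sizes",
    "identify_template",
]


class InconsistentPartitionError(ValueError):
    """A block of the partition mixes +1 and -1 relations."""


@dataclass(frozen=True)
class Partition:
    """Disjoint, exhaustive node blocks, largest first (ties: smallest label)."""

    blocks: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        blocks = tuple(tuple(sorted(int(v) for v in b)) for b in self.blocks)
        blocks = tuple(sorted(blocks, key=lambda b: (-len(b), b)))
        seen: set[int] = set()
        for b in blocks:
            if not b:
                raise ValueError("empty block in partition")
            if seen & set(b):
                raise ValueError("blocks are not disjoint")
            seen |= set(b)
        if seen != set(range(len(seen))):
            raise ValueError("blocks must cover nodes 0..n-1 exactly")
        object.__setattr__(self, "blocks", blocks)

    @property
    def n(self) -> int:
        return sum(len(b) for b in self.blocks)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(len(b) for b in self.blocks)

    def labels(self) -> np.ndarray:
        """Block index of every node."""
        lab = np.empty(self.n, dtype=int)
        for c, b in enumerate(self.blocks):
            lab[list(b)] = c
        return lab

    def as_sets(self) -> frozenset[frozenset[int]]:
        return frozenset(frozenset(b) for b in self.blocks)


@dataclass(frozen=True)
class ClassGraph:
    """Signed digraph between node classes plus class sizes.

    ``rel[a, b]`` is the common sign of the relations from class ``a``
    towards class ``b``; the diagonal entry is 0 (undefined) for
    singleton classes, which have no internal relations.
    """

    sizes: tuple[int, ...]
    rel: np.ndarray

    def __post_init__(self) -> None:
        sizes = tuple(int(v) for v in self.sizes)
        rel = np.array(self.rel, dtype=np.int8)
        c = len(sizes)
        if rel.shape != (c, c):
            raise ValueError("rel must be c x c for c classes")
        if any(v < 1 for v in sizes):
            raise ValueError("class sizes must be >= 1")
        for a in range(c):
            for b in range(c):
                v = rel[a, b]
                if a == b and sizes[a] == 1:
                    if v != 0:
                        raise ValueError("singleton class has no internal sign")
                elif v not in (-1, 1):
                    raise ValueError("rel entries must be -1 or +1")
        rel.flags.writeable = False
        object.__setattr__(self, "sizes", sizes)
        object.__setattr__(self, "rel", rel)

    @property
    def n_classes(self) -> int:
        return len(self.sizes)

    @property
    def n(self) -> int:
        return sum(self.sizes)

    def to_json(self) -> str:
        sym = {1: "+", -1: "-", 0: "."}
        return json.dumps(
            {
                "sizes": list(self.sizes),
                "rel": [[sym[int(v)] for v in row] for row in self.rel],
            }
        )

    def to_dot(self) -> str:
        """Graphviz rendering: solid arrows = friendly, dashed = hostile."""
        lines = ["digraph classes {"]
        for a, sz in enumerate(self.sizes):
            lines.append(f'  c{a + 1} [label="class {a + 1}\\nN={sz}"];')
        for a in range(self.n_classes):
            for b in range(self.n_classes):
                v = int(self.rel[a, b])
                if v == 0:
                    continue
                style = "solid" if v > 0 else "dashed"
                lines.append(f"  c{a + 1} -> c{b + 1} [style={style}];")
        lines.append("}")
        return "\n".join(lines)

    def write_dot(self, path: str | Path) -> None:
        Path(path).write_text(self.to_dot() + "\n")


# ---------------------------------------------------------------------------
# refinement


def _equitable_fixed_point(pos: np.ndarray, colors: np.ndarray) -> np.ndarray:
    """Refine a coloring until it is equitable w.r.t. +out/+in counts."""
    n = pos.shape[0]
    while True:
        uniq = sorted(set(colors.tolist()))
        out_counts = np.stack(
            [pos[:, colors == c].sum(axis=1) for c in uniq], axis=1)
        in_counts = np.stack(
            [pos[colors == c, :].sum(axis=0) for c in uniq], axis=1)
        sigs = [
            (int(colors[i]), tuple(out_counts[i]), tuple(in_counts[i]))
            for i in range(n)
        ]
        ranked = {s: r for r, s in enumerate(sorted(set(sigs)))}
        new = np.array([ranked[s] for s in sigs], dtype=int)
        if len(set(new.tolist())) == len(uniq):
            return new
        colors = new


def _blocks_from_colors(colors: np.ndarray) -> list[list[int]]:
    out: dict[int, list[int]] = {}
    for i, c in enumerate(colors.tolist()):
        out.setdefault(c, []).append(i)
    return [out[c] for c in sorted(out)]


def _find_mixed_block(s: np.ndarray, blocks: list[list[int]]):
    for a, blk_a in enumerate(blocks):
        for b, blk_b in enumerate(blocks):
            sub = s[np.ix_(blk_a, blk_b)]
            if a == b:
                if len(blk_a) == 1:
                    continue
                vals = sub[~np.eye(len(blk_a), dtype=bool)]
            else:
                vals = sub.ravel()
            if vals.size and (vals != vals.flat[0]).any():
                return a, b
    return None


def refine_classes(s: SignMatrix) -> Partition:
    """Coarsest sign-uniform equitable partition of a corner state.

    Starts from the (M(i), L(i)) coloring, refines neighbourhood profiles
    (both out- and in-links; directed states such as CII need both) to a
    fixed point, then enforces sign-uniform blocks as described in the
    module docstring.  The result does not depend on node labels; worst
    case every node ends in its own class.
    """
    m = s.s
    n = s.n
    pos = (m == 1)
    big_m = pos.sum(axis=1)
    big_l = pos.sum(axis=0)
    sigs = sorted(set(zip(big_m.tolist(), big_l.tolist())))
    rank = {sig: r for r, sig in enumerate(sigs)}
    colors = np.array([rank[(int(big_m[i]), int(big_l[i]))] for i in range(n)])
    while True:
        colors = _equitable_fixed_point(pos, colors)
        blocks = _blocks_from_colors(colors)
        mixed = _find_mixed_block(m, blocks)
        if mixed is None:
            return Partition(tuple(tuple(b) for b in blocks))
        a, b = mixed
        nxt = int(colors.max()) + 1
        if a == b:
            blk = blocks[a]
            und = pos[np.ix_(blk, blk)]
            und = und | und.T
            n_comp, comp = connected_components(und, directed=False)
            if n_comp > 1:
                for i, node in enumerate(blk):
                    colors[node] = nxt + int(comp[i])
            else:  # no label-free cut: isolate every member
                for node in blk:
                    colors[node] = nxt
                    nxt += 1
        else:
            # group the members of block b by the sign pattern they receive
            # from block a; if those patterns coincide, the rows of block a
            # must differ instead, so split block a by its out-patterns
            cols = {}
            for node in blocks[b]:
                cols.setdefault(tuple(m[blocks[a], node]), []).append(node)
            if len(cols) > 1:
                for key in sorted(cols):
                    for node in cols[key]:
                        colors[node] = nxt
                    nxt += 1
            else:
                rows = {}
                for node in blocks[a]:
                    rows.setdefault(tuple(m[node, blocks[b]]), []).append(node)
                for key in sorted(rows):
                    for node in rows[key]:
                        colors[node] = nxt
                    nxt += 1


def class_graph(s: SignMatrix, p: Partition) -> ClassGraph:
    """Encode a sign matrix as the signed digraph between partition blocks."""
    if p.n != s.n:
        raise ValueError("partition does not cover the matrix's nodes")
    c = p.n_blocks
    rel = np.zeros((c, c), dtype=np.int8)
    for a, blk_a in enumerate(p.blocks):
        for b, blk_b in enumerate(p.blocks):
            sub = s.s[np.ix_(blk_a, blk_b)]
            if a == b:
                if len(blk_a) == 1:
                    continue
                vals = sub[~np.eye(len(blk_a), dtype=bool)]
            else:
                vals = sub.ravel()
            if (vals != vals.flat[0]).any():
                raise InconsistentPartitionError(
                    f"block ({a}, {b}) mixes +1 and -1 relations")
            rel[a, b] = vals.flat[0]
    return ClassGraph(sizes=p.sizes, rel=rel)


# ---------------------------------------------------------------------------
# canonical form and archetype identification

_SYM = {1: "+", -1: "-", 0: "."}

#: permutation-search budget for exact canonicalisation
_MAX_PERMS = 100_000


def _class_invariant(g: ClassGraph, a: int, with_sizes: bool):
    row = tuple(sorted(int(v) for b, v in enumerate(g.rel[a]) if b != a))
    col = tuple(sorted(int(g.rel[b, a]) for b in range(g.n_classes) if b != a))
    size = g.sizes[a] if with_sizes else 0
    return (size, int(g.rel[a, a]), row, col)


def _key_for_order(g: ClassGraph, order: tuple[int, ...], with_sizes: bool) -> str:
    parts = [str(g.n_classes)]
    if with_sizes:
        parts.append(",".join(str(g.sizes[a]) for a in order))
    parts.append("".join(_SYM[int(g.rel[a, b])] for a in order for b in order))
    return "|".join(parts)


def canonical_key(g: ClassGraph, with_sizes: bool = True) -> str:
    """A string equal for two class graphs iff they are isomorphic.

    ``with_sizes`` controls whether class sizes take part in the
    isomorphism (size-labeled vs unlabeled signed digraphs).  Classes are
    first grouped by local invariants (size, internal sign, sorted row and
    column sign multisets); the key is the lexicographic minimum over all
    invariant-respecting class orders.  If that search space exceeds
    100 000 orders (only possible for graphs with many interchangeable
    classes) the invariant-sorted order is used directly and the key is
    marked with ``~``: still deterministic, but not guaranteed canonical
    across relabelings.
    """
    c = g.n_classes
    inv = [_class_invariant(g, a, with_sizes) for a in range(c)]
    groups: dict[tuple, list[int]] = {}
    for a in range(c):
        groups.setdefault(inv[a], []).append(a)
    ordered_groups = [groups[k] for k in sorted(groups)]
    n_perms = 1
    for grp in ordered_groups:
        n_perms *= factorial(len(grp))
    if n_perms > _MAX_PERMS:
        order = tuple(itertools.chain.from_iterable(ordered_groups))
        return "~" + _key_for_order(g, order, with_sizes)
    best: str | None = None
    for combo in itertools.product(
            *(itertools.permutations(grp) for grp in ordered_groups)):
        order = tuple(itertools.chain.from_iterable(combo))
        key = _key_for_order(g, order, with_sizes)
        if best is None or key < best:
            best = key
    assert best is not None
    return best


def _matches(g: ClassGraph, pattern: np.ndarray, order: tuple[int, ...]) -> bool:
    c = len(order)
    for a in range(c):
        for b in range(c):
            v = int(g.rel[order[a], order[b]])
            if a == b and v == 0:  # singleton class: internal sign undefined
                continue
            if v != int(pattern[a, b]):
                return False
    return True


def identify_template(g: ClassGraph) -> TemplateSpec | None:
    """Match a class graph against the HB/CII/CIII/CIV archetypes.

    Classes are mapped to archetype roles by their sign signature (e.g.
    the CIII class 3 is the one that likes class 1 without reciprocation),
    trying every class permutation; sizes are returned in role order.
    The CIV pattern has an automorphism exchanging classes 1 with 2 and
    3 with 4, so (a, b, c, d) and (b, a, d, c) label the same graph; of
    the valid role assignments the lexicographically largest size tuple
    is returned, making the answer independent of node labels.  Returns
    ``None`` when no archetype fits ("other" states).
    """
    c = g.n_classes
    if c == 1:
        if g.sizes[0] >= 3 and int(g.rel[0, 0]) == 1:
            return TemplateSpec("HB", (g.sizes[0], 0))
        return None
    for kind, n_roles in TEMPLATE_KINDS.items():
        if n_roles != c:
            continue
        pattern = TEMPLATE_PATTERNS[kind]
        hits = [
            tuple(g.sizes[a] for a in order)
            for order in itertools.permutations(range(c))
            if _matches(g, pattern, order)
        ]
        if hits:
            return TemplateSpec(kind, max(hits))
    return None


def canonical_sizes(kind: str, sizes: tuple[int, ...]) -> tuple[int, ...]:
    """The size tuple :func:`identify_template` reports for this archetype.

    Accounts for the pattern automorphisms: HB is symmetric in its two
    classes and CIV admits the exchange (1, 2)(3, 4); CII and CIII have
    none.
    """
    sizes = tuple(int(v) for v in sizes)
    if kind == "HB" and len(sizes) == 2 and 0 not in sizes:
        return max(sizes, tuple(reversed(sizes)))
    if kind == "CIV":
        a, b, c, d = sizes
        return max(sizes, (b, a, d, c))
    return sizes
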