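"""Core data types for directed signed complete networks.

A group of ``n`` actors is modelled as a fully connected directed network
with one signed relation per ordered pair: ``x[i, j]`` is the attitude of
actor ``i`` towards actor ``j``.  Relations are either continuous
(``RelationMatrix``, values in [-1, 1], the state space of the balance
dynamics) or discrete (``SignMatrix``, values in {-1, +1}, the corner
states the dynamics converges to).  Self-relations are not dynamical
variables; the diagonal is stored as 0 and ignored everywhere.

The module also provides the self-evaluation ("looking-glass self") index
``F_i`` and constructors for the four archetype corner configurations
(HB, CII, CIII, CIV) that appear as generic fixed points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

__all__ = [
    "RelationMatrix",
    "SignMatrix",
    "TemplateSpec",
    "TEMPLATE_KINDS",
    "TEMPLATE_PATTERNS",
    "self_evaluation",
    "make_template",
]

#: Archetype kinds in canonical order, with the number of classes of each.
TEMPLATE_KINDS: dict[str, int] = {"HB": 2, "CII": 2, "CIII": 3, "CIV": 4}

#: Block sign pattern of each archetype: entry [a][b] is the sign of the
#: relation of every member of class ``a`` towards every member of class
#: ``b`` (diagonal entries: relations inside the class).
#:
#: HB   -- two internally friendly cliques, mutually hostile, symmetric.
#: CII  -- class 1 a friendly clique; class 2 internally hostile, rejected
#:         by class 1 but liking class 1 back.
#: CIII -- two hostile cliques (1, 2) plus a class 3 of rejected aspirants:
#:         class 3 likes class 1 (unreciprocated) and is liked by class 2
#:         (unreciprocated); class 3 is internally hostile.
#: CIV  -- two hostile cliques (1, 2) plus two internally hostile classes
#:         3 and 4 that like each other; 3 likes 2 and is liked by 1,
#:         4 likes 1 and is liked by 2.
TEMPLATE_PATTERNS: dict[str, np.ndarray] = {
    "HB": np.array([[+1, -1], [-1, +1]], dtype=np.int8),
    "CII": np.array([[+1, -1], [+1, -1]], dtype=np.int8),
    "CIII": np.array(
        [[+1, -1, -1],
         [-1, +1, +1],
         [+1, -1, -1]], dtype=np.int8),
    "CIV": np.array(
        [[+1, -1, +1, -1],
         [-1, +1, -1, +1],
         [-1, +1, -1, +1],
         [+1, -1, +1, -1]], dtype=np.int8),
}


def _check_square(a: np.ndarray) -> int:
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"relation matrix must be square, got shape {a.shape}")
    return a.shape[0]


@dataclass(frozen=True)
class RelationMatrix:
    """Continuous directed relations ``x[i, j]`` in [-1, 1], zero diagonal.

    Parameters
    ----------
    x
        Square array of shape (n, n) with ``|x[i, j]| <= 1`` off the
        diagonal.  The diagonal is forced to zero on construction.
    """

    x: np.ndarray

    def __post_init__(self) -> None:
        x = np.array(self.x, dtype=float)
        n = _check_square(x)
        if n < 3:
            raise ValueError(f"need at least 3 nodes (triads must exist), got n={n}")
        np.fill_diagonal(x, 0.0)
        if np.max(np.abs(x)) > 1.0 + 1e-12:
            raise ValueError("off-diagonal relations must lie in [-1, 1]")
        np.clip(x, -1.0, 1.0, out=x)
        x.flags.writeable = False
        object.__setattr__(self, "x", x)

    @property
    def n(self) -> int:
        return self.x.shape[0]

    def is_symmetric(self, atol: float = 0.0) -> bool:
        return bool(np.allclose(self.x, self.x.T, rtol=0.0, atol=atol))

    def to_csv(self, path: str | Path) -> None:
        """Write as a plain n-by-n CSV; the diagonal is written as 0."""
        np.savetxt(path, self.x, delimiter=",", fmt="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "RelationMatrix":
        return cls(np.loadtxt(path, delimiter=",", ndmin=2))

    def edge_list(self) -> Iterator[tuple[int, int, float]]:
        """Yield (i, j, x_ij) with 1-based node labels, diagonal skipped."""
        n = self.n
        for i in range(n):
            for j in range(n):
                if i != j:
                    yield (i + 1, j + 1, float(self.x[i, j]))


@dataclass(frozen=True)
class SignMatrix:
    """Discrete directed relations ``s[i, j]`` in {-1, +1}, zero diagonal."""

    s: np.ndarray

    def __post_init__(self) -> None:
        s_in = np.asarray(self.s)
        n = _check_square(s_in)
        if n < 3:
            raise ValueError(f"need at least 3 nodes (triads must exist), got n={n}")
        s = np.array(s_in, dtype=np.int8)
        if not np.array_equal(s, s_in):  # reject e.g. 0.5 silently truncated
            raise ValueError("sign matrix entries must be integers -1/+1")
        np.fill_diagonal(s, 0)
        off = ~np.eye(n, dtype=bool)
        if not np.all(np.abs(s[off]) == 1):
            raise ValueError("off-diagonal entries of a sign matrix must be exactly -1 or +1")
        s.flags.writeable = False
        object.__setattr__(self, "s", s)

    @property
    def n(self) -> int:
        return self.s.shape[0]

    def is_symmetric(self) -> bool:
        return bool(np.array_equal(self.s, self.s.T))

    def permuted(self, perm: np.ndarray) -> "SignMatrix":
        """Relabel nodes: node ``perm[i]`` of the result is node ``i`` here."""
        p = np.asarray(perm)
        inv = np.argsort(p)
        return SignMatrix(self.s[np.ix_(inv, inv)])

    def to_relation(self) -> RelationMatrix:
        return RelationMatrix(self.s.astype(float))

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(path, self.s, delimiter=",", fmt="%d")

    @classmethod
    def from_csv(cls, path: str | Path) -> "SignMatrix":
        return cls(np.loadtxt(path, delimiter=",", dtype=int, ndmin=2))

    def edge_list(self) -> Iterator[tuple[int, int, int]]:
        n = self.n
        for i in range(n):
            for j in range(n):
                if i != j:
                    yield (i + 1, j + 1, int(self.s[i, j]))


@dataclass(frozen=True)
class TemplateSpec:
    """An archetype identifier plus its class sizes.

    ``kind`` is one of HB, CII (two classes), CIII (three), CIV (four);
    ``sizes`` gives (N1, N2[, N3[, N4]]).  Every class must be nonempty,
    with one exception: HB with N2 = 0 is the degenerate single-clique
    (all-friendly) state.
    """

    kind: str
    sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.kind not in TEMPLATE_KINDS:
            raise ValueError(f"unknown template kind {self.kind!r}")
        sizes = tuple(int(v) for v in self.sizes)
        object.__setattr__(self, "sizes", sizes)
        c = TEMPLATE_KINDS[self.kind]
        if len(sizes) != c:
            raise ValueError(f"{self.kind} takes {c} class sizes, got {len(sizes)}")
        if any(v < 0 for v in sizes):
            raise ValueError("class sizes must be non-negative")
        if 0 in sizes and not (self.kind == "HB" and sizes[0] > 0 and sizes[1] == 0):
            raise ValueError(
                "empty classes are only permitted in the degenerate HB (N2 = 0) case")
        if self.n < 3:
            raise ValueError("template must have at least 3 nodes")

    @property
    def n(self) -> int:
        return sum(self.sizes)

    @property
    def n_classes(self) -> int:
        return TEMPLATE_KINDS[self.kind]


def self_evaluation(s: SignMatrix) -> np.ndarray:
    """Self-evaluation index F_i of every actor.

    ``F_i = (1/2) * sum_k (1 + s_ik) * s_ki``: the sum of the reciprocal
    relations ``s_ki`` over the actors ``k`` whom ``i`` likes
    (``s_ik = +1``); disliked actors contribute nothing.  ``F_i`` is an
    integer in [-(n-1), n-1]; it is negative when the liking of actor
    ``i`` is mostly unreciprocated.
    """
    if not isinstance(s, SignMatrix):
        s = SignMatrix(np.asarray(s))
    m = s.s.astype(np.int64)
    # diagonal is 0, so the k = i term vanishes on its own
    f = ((1 + m) * m.T).sum(axis=1) // 2
    return f


def make_template(spec: TemplateSpec) -> SignMatrix:
    """Construct the corner sign matrix of an archetype configuration.

    Nodes are ordered class-contiguously (all of class 1 first, then
    class 2, ...).  Block signs follow :data:`TEMPLATE_PATTERNS`.
    """
    pattern = TEMPLATE_PATTERNS[spec.kind]
    sizes = [v for v in spec.sizes]
    labels = np.repeat(np.arange(len(sizes)), sizes)
    s = pattern[np.ix_(labels, labels)].copy()
    np.fill_diagonal(s, 0)
    return SignMatrix(s)
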