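"""Stationarity of corner states and closed-form archetype analysis.

A corner sign matrix is a fixed point that the continuous dynamics cannot
leave in the direction of any single relation iff every relation agrees
with its third-party vote:

    s_ij = sign( T_ij ),   T_ij = sum_{k != i, j} s_ik s_kj .

For odd n the vote T_ij (a sum of n - 2 terms of +-1) is never zero, so
stationarity is unambiguous; for even n exact ties are possible and are
reported separately, never silently resolved.

For the archetype configurations the vote can be evaluated in closed
form, which yields one binding inequality per kind:

    HB    always stationary,
    CII   N1 > N2 + 2,
    CIII  N1 + N2 > N3 + 2,
    CIV   N1 + N2 > N3 + N4 + 2,

(the remaining links give strictly weaker inequalities), together with
closed-form per-class self-evaluation values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .signed_network import SignMatrix, TemplateSpec

__all__ = [
    "StabilityReport",
    "is_stationary",
    "is_balanced",
    "template_stable",
    "template_self_evaluations",
]


@dataclass(frozen=True)
class StabilityReport:
    """Outcome of the sign stationarity test.

    ``violating_links`` lists ordered pairs (i, j) with
    sign(T_ij) != s_ij (0-based); ``zero_sum_links`` lists pairs with
    T_ij exactly 0 (possible only for even n).  The state is stationary
    iff both lists are empty.
    """

    stationary: bool
    violating_links: tuple[tuple[int, int], ...]
    zero_sum_links: tuple[tuple[int, int], ...]

    def to_json(self) -> str:
        return json.dumps(
            {
                "stationary": self.stationary,
                "violating_links": [list(p) for p in self.violating_links],
                "zero_sum_links": [list(p) for p in self.zero_sum_links],
            }
        )


def triad_votes(s: SignMatrix) -> np.ndarray:
    """The matrix T_ij = sum_{k != i, j} s_ik s_kj (diagonal zeroed)."""
    m = s.s.astype(np.int64)
    t = m @ m  # zero diagonal removes the k = i and k = j terms
    np.fill_diagonal(t, 0)
    return t


def is_stationary(s: SignMatrix) -> StabilityReport:
    """Test the corner fixed-point condition s_ij = sign(T_ij)."""
    t = triad_votes(s)
    n = s.n
    viol = []
    zeros = []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if t[i, j] == 0:
                zeros.append((i, j))
            elif np.sign(t[i, j]) != s.s[i, j]:
                viol.append((i, j))
    return StabilityReport(
        stationary=not viol and not zeros,
        violating_links=tuple(viol),
        zero_sum_links=tuple(zeros),
    )


def is_balanced(s: SignMatrix) -> bool:
    """True iff the matrix is symmetric and every triad product is +1.

    This is the classical structural-balance condition; symmetric
    stationary states that fail it are symmetric jammed states.
    """
    if not s.is_symmetric():
        return False
    m = s.s.astype(np.int64)
    n = s.n
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                if m[i, j] * m[j, k] * m[k, i] != 1:
                    return False
    return True


def _reduce_trailing_zeros(spec_kind: str, sizes: tuple[int, ...]):
    """Drop empty trailing classes, renaming to the lower archetype.

    CIV with N4 = 0 has the sign structure of CIII with classes 1 and 2
    exchanged; CIII with N3 = 0 and CII with N2 = 0 both collapse to HB.
    """
    kind, sz = spec_kind, tuple(sizes)
    if kind == "CIV" and sz[3] == 0:
        kind, sz = "CIII", (sz[1], sz[0], sz[2])
    if kind == "CIII" and sz[2] == 0:
        kind, sz = "HB", (sz[0], sz[1])
    if kind == "CII" and sz[1] == 0:
        kind = "HB"
    return kind, sz


def template_stable(spec: TemplateSpec | tuple[str, tuple[int, ...]]) -> bool:
    """Closed-form stationarity of an archetype configuration.

    Accepts a :class:`TemplateSpec` or a raw ``(kind, sizes)`` pair; raw
    pairs may carry empty trailing classes, which delegate to the lower
    archetype they degenerate to.
    """
    if isinstance(spec, TemplateSpec):
        kind, sizes = spec.kind, spec.sizes
    else:
        kind, sizes = spec
        sizes = tuple(int(v) for v in sizes)
    kind, sizes = _reduce_trailing_zeros(kind, sizes)
    if kind == "HB":
        return True
    if kind == "CII":
        return sizes[0] > sizes[1] + 2
    if kind == "CIII":
        return sizes[0] + sizes[1] > sizes[2] + 2
    if kind == "CIV":
        return sizes[0] + sizes[1] > sizes[2] + sizes[3] + 2
    raise ValueError(f"unknown template kind {kind!r}")


def template_self_evaluations(spec: TemplateSpec) -> tuple[int, ...]:
    """Closed-form per-class self-evaluation F of an archetype.

    HB: (N1 - 1, N2 - 1); CII: (N1 - 1, -N1);
    CIII: (N1 - 1, N2 - N3 - 1, -N1);
    CIV: (N1 - N3 - 1, N2 - N4 - 1, N4 - N2, N3 - N1).
    These equal the direct evaluation of F on the constructed matrix.
    """
    n1, n2, *rest = spec.sizes
    if spec.kind == "HB":
        if n2 == 0:
            return (n1 - 1,)
        return (n1 - 1, n2 - 1)
    if spec.kind == "CII":
        return (n1 - 1, -n1)
    if spec.kind == "CIII":
        n3 = rest[0]
        return (n1 - 1, n2 - n3 - 1, -n1)
    if spec.kind == "CIV":
        n3, n4 = rest
        return (n1 - n3 - 1, n2 - n4 - 1, n4 - n2, n3 - n1)
    raise ValueError(f"unknown template kind {spec.kind!r}")
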