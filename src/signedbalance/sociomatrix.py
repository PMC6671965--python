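"""Sociometric matrix ingestion and the signed-combination workflow.

Classical sociometric instruments record two valued, non-symmetric
matrices per relation: X (positive nominations, e.g. "liking") and Y
(negative nominations, "disliking").  They are combined into one signed
relation matrix as (X - Y) / scale, with the scale chosen so the result
lies in (-1, 1); that matrix then serves as the initial condition of the
balance dynamics, and the converged corner is classified like any
synthetic run.

Supported inputs are plain CSV and the UCINET DL full-matrix dialect
(the format of the Sampson monastery matrices).  Actor indices in all
reports are 1-based and refer to the original file ordering, also after
actors are dropped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .classification import ClassGraph, class_graph, identify_template, refine_classes
from .dynamics import DEFAULT_T_MAX, DEFAULT_TOL, evolve
from .signed_network import RelationMatrix, TemplateSpec, self_evaluation

__all__ = [
    "ValuedMatrix",
    "SociomatrixReport",
    "read_matrix",
    "combine_signed",
    "drop_actors",
    "analyze_sociomatrix",
]


class ParseError(ValueError):
    """Malformed sociomatrix file; the message names the offending line."""


@dataclass(frozen=True)
class ValuedMatrix:
    """A square valued sociomatrix with optional actor labels.

    ``origin`` maps row positions to 1-based actor indices of the source
    file, so reports stay meaningful after rows are dropped.
    """

    v: np.ndarray
    labels: tuple[str, ...] | None = None
    origin: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        v = np.array(self.v, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"sociomatrix must be square, got shape {v.shape}")
        v.flags.writeable = False
        object.__setattr__(self, "v", v)
        if self.labels is not None:
            labels = tuple(str(x) for x in self.labels)
            if len(labels) != v.shape[0]:
                raise ValueError("labels length must equal matrix size")
            object.__setattr__(self, "labels", labels)
        origin = self.origin
        if origin is None:
            origin = tuple(range(1, v.shape[0] + 1))
        if len(origin) != v.shape[0]:
            raise ValueError("origin length must equal matrix size")
        object.__setattr__(self, "origin", tuple(int(i) for i in origin))

    @property
    def n(self) -> int:
        return self.v.shape[0]

    def to_csv(self, path: str | Path) -> None:
        lines = []
        if self.labels is not None:
            lines.append(",".join(self.labels))
        for row in self.v:
            lines.append(",".join(f"{x:g}" for x in row))
        Path(path).write_text("\n".join(lines) + "\n")


def _read_csv(path: Path) -> ValuedMatrix:
    raw = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not raw:
        raise ParseError(f"{path}: empty file")
    labels: tuple[str, ...] | None = None
    first = raw[0].split(",")
    try:
        [float(tok) for tok in first]
        start = 0
    except ValueError:  # header row of actor labels
        labels = tuple(tok.strip() for tok in first)
        start = 1
    rows = []
    for lineno, ln in enumerate(raw[start:], start=start + 1):
        toks = ln.split(",")
        try:
            rows.append([float(t) for t in toks])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric entry") from exc
    n = len(rows)
    if any(len(r) != n for r in rows):
        raise ParseError(f"{path}: data is not a square matrix ({n} rows)")
    if labels is not None and len(labels) != n:
        raise ParseError(f"{path}: header has {len(labels)} labels for {n} rows")
    return ValuedMatrix(np.array(rows), labels=labels)


def _read_dl(path: Path) -> ValuedMatrix:
    """UCINET DL, full-matrix dialect only (the Sampson files' format)."""
    text = path.read_text()
    lines = text.splitlines()
    if not lines or not lines[0].lstrip().lower().startswith("dl"):
        raise ParseError(f"{path}:1: not a DL file (missing 'dl' header)")
    m = re.search(r"n\s*[=:]\s*(\d+)", lines[0], flags=re.IGNORECASE)
    if m is None:
        raise ParseError(f"{path}:1: DL header lacks an n=<count> declaration")
    n = int(m.group(1))
    fmt = re.search(r"format\s*[=:]\s*(\S+)", text, flags=re.IGNORECASE)
    if fmt and fmt.group(1).lower().rstrip(",") not in ("fullmatrix", "full"):
        raise ParseError(
            f"{path}: only the full-matrix DL dialect is supported, "
            f"got format={fmt.group(1)}")
    labels: tuple[str, ...] | None = None
    section = None
    label_toks: list[str] = []
    values: list[float] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        stripped = ln.strip()
        if not stripped:
            continue
        low = stripped.lower()
        if low.startswith("labels"):
            section = "labels"
            continue
        if low.startswith("data"):
            section = "data"
            continue
        if low.startswith("format"):
            continue
        if section == "labels":
            label_toks.extend(t for t in re.split(r"[,\s]+", stripped) if t)
        elif section == "data":
            for tok in stripped.split():
                try:
                    values.append(float(tok))
                except ValueError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: non-numeric data entry {tok!r}"
                    ) from exc
        else:
            raise ParseError(f"{path}:{lineno}: unexpected content before a "
                             "'labels:' or 'data:' section")
    if label_toks:
        if len(label_toks) != n:
            raise ParseError(
                f"{path}: {len(label_toks)} labels for declared n={n}")
        labels = tuple(label_toks)
    if len(values) != n * n:
        raise ParseError(
            f"{path}: expected {n * n} data values for n={n}, got {len(values)}")
    return ValuedMatrix(np.array(values).reshape(n, n), labels=labels)


def read_matrix(path: str | Path, format: str | None = None) -> ValuedMatrix:
    """Read a valued sociomatrix from a CSV or UCINET DL file.

    ``format`` is "csv" or "dl"; when omitted it is inferred from the
    file suffix (.dl) or a leading "dl" header line.
    """
    p = Path(path)
    if format is None:
        if p.suffix.lower() == ".dl":
            format = "dl"
        else:
            head = p.read_text().lstrip()[:2].lower()
            format = "dl" if head == "dl" else "csv"
    if format == "dl":
        return _read_dl(p)
    if format == "csv":
        return _read_csv(p)
    raise ValueError(f"unknown sociomatrix format {format!r}")


def combine_signed(x: ValuedMatrix, y: ValuedMatrix, scale: float = 5.0) -> RelationMatrix:
    """Signed relations (X - Y) / scale from positive/negative nominations.

    The scale must exceed the largest |x - y| so the result stays inside
    (-1, 1); out-of-range entries raise rather than clip, since they
    signal a misread value convention.
    """
    if x.v.shape != y.v.shape:
        raise ValueError(
            f"matrices differ in shape: {x.v.shape} vs {y.v.shape}")
    r = (x.v - y.v) / float(scale)
    off = ~np.eye(x.n, dtype=bool)
    if np.any(np.abs(r[off]) > 1.0):
        i, j = np.unravel_index(np.argmax(np.abs(r)), r.shape)
        raise ValueError(
            f"combined relation out of (-1, 1) at actors "
            f"({x.origin[i]}, {x.origin[j]}): {r[i, j]:g}; increase scale")
    r = r.copy()
    np.fill_diagonal(r, 0.0)
    return RelationMatrix(r)


def drop_actors(m: ValuedMatrix, indices: Sequence[int]) -> ValuedMatrix:
    """Remove actors by their 1-based original indices (rows and columns)."""
    drop = set(int(i) for i in indices)
    bad = drop - set(m.origin)
    if bad:
        raise ValueError(f"no such actors to drop: {sorted(bad)}")
    keep = [pos for pos, orig in enumerate(m.origin) if orig not in drop]
    if len(keep) < 3:
        raise ValueError("dropping these actors leaves fewer than 3")
    labels = tuple(m.labels[i] for i in keep) if m.labels else None
    return ValuedMatrix(
        m.v[np.ix_(keep, keep)],
        labels=labels,
        origin=tuple(m.origin[i] for i in keep),
    )


@dataclass(frozen=True)
class SociomatrixReport:
    """Outcome of evolving and classifying one sociometric matrix.

    ``f`` holds the per-actor self-evaluation index; ``low_f_actors``
    lists the 1-based original indices of actors with F < 0.  When the
    dynamics does not reach a corner (the matrix is not dense enough to
    settle into a fully connected signed state) only ``converged`` and
    ``t_end`` are meaningful.
    """

    converged: bool
    t_end: float
    origin: tuple[int, ...]
    graph: ClassGraph | None = None
    template: TemplateSpec | None = None
    f: tuple[int, ...] | None = None
    low_f_actors: tuple[int, ...] | None = None

    def to_dict(self) -> dict:
        out: dict = {"converged": self.converged, "t_end": self.t_end}
        if self.converged:
            assert self.graph is not None and self.f is not None
            out["class_sizes"] = list(self.graph.sizes)
            out["template"] = (
                {"kind": self.template.kind, "sizes": list(self.template.sizes)}
                if self.template is not None else None)
            out["F"] = {str(a): int(v) for a, v in zip(self.origin, self.f)}
            out["low_F_actors"] = list(self.low_f_actors or ())
        return out


def analyze_sociomatrix(
    r: RelationMatrix,
    origin: Sequence[int] | None = None,
    tol: float = DEFAULT_TOL,
    t_max: float = DEFAULT_T_MAX,
) -> SociomatrixReport:
    """Evolve a signed sociomatrix to a corner and classify the outcome."""
    origin = tuple(origin) if origin is not None else tuple(range(1, r.n + 1))
    if len(origin) != r.n:
        raise ValueError("origin length must equal matrix size")
    ev = evolve(r, tol=tol, t_max=t_max)
    if not ev.converged:
        return SociomatrixReport(converged=False, t_end=ev.t_end, origin=origin)
    s = ev.sign
    assert s is not None
    part = refine_classes(s)
    graph = class_graph(s, part)
    template = identify_template(graph)
    f = self_evaluation(s)
    low = tuple(a for a, v in zip(origin, f) if v < 0)
    return SociomatrixReport(
        converged=True,
        t_end=ev.t_end,
        origin=origin,
        graph=graph,
        template=template,
        f=tuple(int(v) for v in f),
        low_f_actors=low,
    )
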