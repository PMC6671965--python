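"""Monte-Carlo ensembles of the balance dynamics and their statistics.

An ensemble run draws ``k_runs`` independent initial relation matrices
with entries uniform on (-1, 1), integrates each to a corner (or gives
up at ``t_max``), classifies every converged corner into a class graph,
and tallies class graphs by canonical key.  The tallies reproduce the
frequency tables of archetype configurations and the asymmetric-state
fractions; a Stirling-number side computation quantifies why four-class
states crowd out three-class states as the group grows.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd

from .classification import canonical_key, class_graph, identify_template, refine_classes
from .dynamics import DEFAULT_T_MAX, DEFAULT_TOL, evolve
from .signed_network import RelationMatrix
from .stability import is_stationary

__all__ = [
    "RunRecord",
    "EnsembleResult",
    "random_initial",
    "run_ensemble",
    "frequency_table",
    "rank_frequency",
    "rank_collapse_exponent",
    "stirling2",
    "partition_ratio",
]

logger = logging.getLogger(__name__)

_KIND_ORDER = {"CIII": 0, "CIV": 1, "HB": 2, "CII": 3, "other": 4}


def random_initial(n: int, rng: np.random.Generator,
                   symmetric: bool = False) -> RelationMatrix:
    """Random initial relations, i.i.d. uniform on (-1, 1) off the diagonal.

    With ``symmetric=True`` the upper triangle is mirrored, which the
    dynamics then preserves exactly.
    """
    x = rng.uniform(-1.0, 1.0, size=(n, n))
    if symmetric:
        iu = np.triu_indices(n, k=1)
        x[(iu[1], iu[0])] = x[iu]
    np.fill_diagonal(x, 0.0)
    return RelationMatrix(x)


@dataclass(frozen=True)
class RunRecord:
    """Per-run outcome of an ensemble."""

    index: int
    converged: bool
    t_end: float
    kind: str | None = None          # HB / CII / CIII / CIV / "other"
    sizes: tuple[int, ...] | None = None  # class sizes in archetype role order
    key: str | None = None           # canonical class-graph key (with sizes)
    asymmetric: bool | None = None   # final sign matrix != its transpose
    degenerate: bool = False         # zero third-party votes (even n only)


@dataclass
class EnsembleResult:
    """Tallies and per-run records of one Monte-Carlo ensemble."""

    n: int
    k_runs: int
    seed: int
    records: list[RunRecord]
    tallies: Counter = field(default_factory=Counter)
    key_meta: dict[str, tuple[str, tuple[int, ...]]] = field(default_factory=dict)

    @property
    def n_converged(self) -> int:
        return sum(1 for r in self.records if r.converged)

    @property
    def n_other(self) -> int:
        return sum(1 for r in self.records if r.converged and r.kind == "other")

    def count(self, kind: str, sizes: Sequence[int] | None = None) -> int:
        """Number of converged runs ending in ``kind`` (and ``sizes`` if given)."""
        sizes = None if sizes is None else tuple(sizes)
        return sum(
            1 for r in self.records
            if r.converged and r.kind == kind
            and (sizes is None or r.sizes == sizes)
        )

    def fraction_asymmetric(self, of_converged: bool = True) -> float:
        """Share of asymmetric final states, over converged runs or all runs."""
        hits = sum(1 for r in self.records if r.converged and r.asymmetric)
        denom = self.n_converged if of_converged else self.k_runs
        return hits / denom if denom else float("nan")

    def fraction_kinds(self, kinds: Sequence[str],
                       of_converged: bool = False) -> float:
        """Share of runs ending in any of ``kinds`` (default: of all runs)."""
        hits = sum(1 for r in self.records if r.converged and r.kind in kinds)
        denom = self.n_converged if of_converged else self.k_runs
        return hits / denom if denom else float("nan")

    def summary(self) -> dict:
        return {
            "n": self.n,
            "k_runs": self.k_runs,
            "seed": self.seed,
            "converged": self.n_converged,
            "converged_fraction": self.n_converged / self.k_runs,
            "asymmetric_of_converged": self.fraction_asymmetric(True),
            "asymmetric_of_all": self.fraction_asymmetric(False),
            "ciii_civ_of_converged": self.fraction_kinds(("CIII", "CIV"), True),
            "ciii_civ_of_all": self.fraction_kinds(("CIII", "CIV"), False),
            "other": self.n_other,
        }


def run_seed(master_seed: int, index: int) -> np.random.Generator:
    """Counter-based per-run stream: reproducible and order-independent."""
    return np.random.default_rng([int(master_seed), int(index)])


def run_ensemble(
    n: int,
    k_runs: int,
    seed: int,
    tol: float = DEFAULT_TOL,
    t_max: float = DEFAULT_T_MAX,
    rtol: float = 1e-10,
    atol: float = 1e-10,
    symmetric: bool = False,
    log_every: int = 1000,
) -> EnsembleResult:
    """Run the full pipeline (init, evolve, discretise, classify) k times.

    Each run uses an independent random stream derived from
    ``(seed, run_index)``, so the result is reproducible for a given
    master seed regardless of execution order.  Integration failures and
    runs that exceed ``t_max`` are recorded as non-converged, never
    raised.
    """
    result = EnsembleResult(n=n, k_runs=k_runs, seed=seed, records=[])
    for i in range(k_runs):
        x0 = random_initial(n, run_seed(seed, i), symmetric=symmetric)
        try:
            ev = evolve(x0, tol=tol, t_max=t_max, rtol=rtol, atol=atol)
        except FloatingPointError:
            result.records.append(RunRecord(index=i, converged=False, t_end=np.nan))
            continue
        if not ev.converged:
            result.records.append(
                RunRecord(index=i, converged=False, t_end=ev.t_end))
            continue
        s = ev.sign
        assert s is not None
        report = is_stationary(s)
        part = refine_classes(s)
        graph = class_graph(s, part)
        tpl = identify_template(graph)
        kind = tpl.kind if tpl is not None else "other"
        sizes = tpl.sizes if tpl is not None else part.sizes
        key = canonical_key(graph, with_sizes=True)
        result.tallies[key] += 1
        result.key_meta.setdefault(key, (kind, sizes))
        result.records.append(
            RunRecord(
                index=i,
                converged=True,
                t_end=ev.t_end,
                kind=kind,
                sizes=sizes,
                key=key,
                asymmetric=not s.is_symmetric(),
                degenerate=bool(report.zero_sum_links),
            )
        )
        if log_every and (i + 1) % log_every == 0:
            logger.info("ensemble n=%d: %d/%d runs done", n, i + 1, k_runs)
    return result


def frequency_table(result: EnsembleResult) -> pd.DataFrame:
    """Archetype frequency table: columns kind, N1..N4, count.

    Rows are sorted by archetype (CIII before CIV, then HB, CII) and by
    count descending; CIII rows carry N4 = 0, two-class rows N3 = N4 = 0.
    Unmatched ("other") class graphs have no role order and are excluded.
    """
    rows = []
    for key, cnt in result.tallies.items():
        kind, sizes = result.key_meta[key]
        if kind == "other":
            continue
        padded = tuple(sizes) + (0,) * (4 - len(sizes))
        rows.append((kind, *padded, cnt))
    rows.sort(key=lambda r: (_KIND_ORDER[r[0]], -r[5], r[1:5]))
    return pd.DataFrame(rows, columns=["kind", "N1", "N2", "N3", "N4", "count"])


def rank_frequency(result: EnsembleResult) -> list[tuple[int, int]]:
    """(rank, count) pairs, counts ascending, higher rank = more frequent."""
    counts = sorted(result.tallies.values())
    return [(rank, cnt) for rank, cnt in enumerate(counts, start=1)]


def rank_collapse_exponent(
    results: Sequence[EnsembleResult],
    alphas: np.ndarray | None = None,
) -> float:
    """Exponent that best collapses rank-frequency curves across sizes.

    For each ensemble the curve log(count) vs log(rank * n**-alpha) is
    interpolated on a common grid; the returned alpha minimises the
    summed squared spread between the curves.  Needs at least two
    ensembles of different n.
    """
    if len(results) < 2 or len({r.n for r in results}) < 2:
        raise ValueError("need ensembles at two or more network sizes")
    if alphas is None:
        alphas = np.linspace(0.0, 4.0, 401)
    curves = []
    for res in results:
        pairs = rank_frequency(res)
        ranks = np.array([p[0] for p in pairs], dtype=float)
        counts = np.array([p[1] for p in pairs], dtype=float)
        curves.append((np.log(ranks), np.log(counts), np.log(res.n)))
    best_alpha, best_cost = float(alphas[0]), np.inf
    for alpha in alphas:
        los, his = [], []
        for lr, _, ln in curves:
            scaled = lr - alpha * ln
            los.append(scaled.min())
            his.append(scaled.max())
        lo, hi = max(los), min(his)
        if hi <= lo:
            continue
        grid = np.linspace(lo, hi, 50)
        interp = [np.interp(grid, lr - alpha * ln, lc) for lr, lc, ln in curves]
        cost = float(np.var(np.stack(interp), axis=0).sum())
        if cost < best_cost:
            best_cost, best_alpha = cost, float(alpha)
    return best_alpha


@lru_cache(maxsize=None)
def _stirling2(n: int, k: int) -> int:
    if k > n:
        return 0
    if n == 0:
        return 1
    if k == 0:
        return 0
    return k * _stirling2(n - 1, k) + _stirling2(n - 1, k - 1)


def stirling2(n: int, k: int) -> int:
    """Stirling number of the second kind S(n, k), exact integers.

    Computed by the recurrence S(n, k) = k S(n-1, k) + S(n-1, k-1):
    the number of partitions of n labeled elements into k nonempty
    unlabeled sets.
    """
    if n < 0 or k < 0 or k > n:
        raise ValueError(f"need 0 <= k <= n, got n={n}, k={k}")
    return _stirling2(n, k)


def partition_ratio(n: int) -> float:
    """S(n, 4) / S(n, 3): how fast four-class splits outgrow three-class."""
    return stirling2(n, 4) / stirling2(n, 3)
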