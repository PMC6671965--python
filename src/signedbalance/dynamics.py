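"""Time evolution of continuous relations to corner fixed points.

The coupled equations

    d x_ij / dt = (1 - x_ij^2) * sum_{k != i, j} x_ik x_kj

drive each relation towards the sign favoured by the third parties k:
a common friend or common enemy of i and j pushes x_ij up, a mixed pair
pushes it down, and the saturating factor (1 - x_ij^2) confines every
relation to [-1, 1].  Generic trajectories end at a hypercube corner
(all x_ij = +-1); the corner is read off as a :class:`SignMatrix` once
every relation is within a stop tolerance of +-1.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._integrate import dopri_evolve, rhs_matrix
from .signed_network import RelationMatrix, SignMatrix

__all__ = ["EvolutionResult", "rhs", "evolve", "discretize", "NotConvergedError"]

#: Stop criterion: the run has reached a corner when max |1 - |x_ij|| <= tol.
DEFAULT_TOL = 1e-8
#: Default integration horizon in model-time units.  Corners are
#: typically reached before t ~ 20 for n <= 11; the cutoff at 40 leaves
#: the slowest 2-3% of random-start runs (long saddle passages) counted
#: as non-converged, consistent with generic convergence rates around
#: 97% at these sizes.
DEFAULT_T_MAX = 40.0


class NotConvergedError(RuntimeError):
    """Raised when a corner state is requested from a non-corner matrix."""


@dataclass(frozen=True)
class EvolutionResult:
    """Outcome of one integration of the balance dynamics.

    ``converged`` is true iff the final state satisfies the corner
    criterion ``max_ij |1 - |x_ij|| <= tol``; only then is ``sign`` set.
    ``t_end`` is the (dimensionless) model time reached.
    """

    final: RelationMatrix
    converged: bool
    t_end: float
    tol: float
    sign: SignMatrix | None = None

    def to_files(self, matrix_path: str | Path, meta_path: str | Path) -> None:
        """Write the final matrix as CSV and the run metadata as JSON."""
        self.final.to_csv(matrix_path)
        meta = {
            "converged": self.converged,
            "t_end": self.t_end,
            "tol": self.tol,
            "n": self.final.n,
        }
        Path(meta_path).write_text(json.dumps(meta, indent=2) + "\n")


def rhs(x: RelationMatrix | np.ndarray) -> np.ndarray:
    """Derivative matrix d x_ij / dt; the diagonal of the result is zero.

    The sum over third parties runs over exactly n - 2 values of k
    (k != i and k != j); with a zero diagonal it equals (x @ x)_ij.
    """
    if isinstance(x, RelationMatrix):
        x = x.x
    return rhs_matrix(x)


def evolve(
    x0: RelationMatrix,
    tol: float = DEFAULT_TOL,
    t_max: float = DEFAULT_T_MAX,
    rtol: float = 1e-10,
    atol: float = 1e-10,
) -> EvolutionResult:
    """Integrate the balance dynamics from ``x0`` until a corner or ``t_max``.

    Parameters
    ----------
    x0
        Initial relations, all in [-1, 1].
    tol
        Corner stop criterion on max |1 - |x_ij||.
    t_max
        Horizon after which the run is reported as not converged (such
        runs do occur for generic initial conditions and are counted, not
        raised).
    rtol, atol
        Local error tolerances of the adaptive Dormand-Prince stepper;
        kept tighter than ``tol`` so that the stop test, not the solver,
        limits accuracy.

    Notes
    -----
    For even ``n`` the third-party sum at a corner can be exactly zero,
    which makes stationarity of the corner ill-defined; a warning is
    emitted (the classification of such runs reports them as degenerate).
    """
    if not isinstance(x0, RelationMatrix):
        x0 = RelationMatrix(np.asarray(x0, dtype=float))
    if x0.n % 2 == 0:
        warnings.warn(
            "even node count: corner stationarity can be ambiguous "
            "(third-party sums over n - 2 terms of +-1 may vanish)",
            stacklevel=2,
        )
    x_fin, t_end, status = dopri_evolve(x0.x, tol, float(t_max), rtol, atol)
    if status == 2:
        raise FloatingPointError(
            "relation drifted beyond 1 + 1e-6 or the step size collapsed; "
            "the integrator tolerances are misconfigured")
    final = RelationMatrix(x_fin)
    converged = status == 0
    sign = discretize(final, tol) if converged else None
    return EvolutionResult(final=final, converged=converged, t_end=t_end,
                           tol=tol, sign=sign)


def discretize(x: RelationMatrix, tol: float = DEFAULT_TOL) -> SignMatrix:
    """Read the corner sign matrix off a converged state.

    Every off-diagonal entry must satisfy |x_ij| >= 1 - tol; otherwise the
    state is not a corner and :class:`NotConvergedError` is raised.
    """
    if not isinstance(x, RelationMatrix):
        x = RelationMatrix(np.asarray(x, dtype=float))
    a = np.abs(x.x)
    off = ~np.eye(x.n, dtype=bool)
    if np.any(a[off] < 1.0 - tol):
        worst = float(np.min(a[off]))
        raise NotConvergedError(
            f"matrix is not at a corner: min |x_ij| = {worst:.6g} < 1 - tol")
    s = np.where(x.x > 0, 1, -1).astype(np.int8)
    np.fill_diagonal(s, 0)
    return SignMatrix(s)
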