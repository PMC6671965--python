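"""Adaptive Dormand-Prince 5(4) stepper specialised to the balance dynamics.

The right-hand side d x_ij/dt = (1 - x_ij^2) * sum_{k != i,j} x_ik x_kj
is evaluated on the full n-by-n matrix with a zero diagonal, in which case
the constrained sum is exactly the (i, j) entry of the matrix product
x @ x.  The stepper integrates until every off-diagonal entry is within
``corner_tol`` of +-1 (a hypercube corner) or until ``t_max``.

The loop is compiled with numba when available; the same source runs as
plain Python otherwise, so results are identical either way.  Accuracy is
controlled by an embedded 4th-order error estimate with the usual PI-free
step-size rule; a cross-check against ``scipy.integrate.solve_ivp`` lives
in the test suite.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap

# Dormand-Prince RK5(4) tableau (the pair used by MATLAB's ode45 and
# scipy's RK45).  E is the difference between the 5th- and 4th-order
# weights, used for the error estimate.
_C = np.array([0.0, 1 / 5, 3 / 10, 4 / 5, 8 / 9, 1.0, 1.0])
_A = np.array(
    [
        [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
        [1 / 5, 0.0, 0.0, 0.0, 0.0, 0.0],
        [3 / 40, 9 / 40, 0.0, 0.0, 0.0, 0.0],
        [44 / 45, -56 / 15, 32 / 9, 0.0, 0.0, 0.0],
        [19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729, 0.0, 0.0],
        [9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656, 0.0],
    ]
)
_B = np.array([35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84])
_E = np.array(
    [71 / 57600, 0.0, -71 / 16695, 71 / 1920, -17253 / 339200, 22 / 525, -1 / 40]
)


@njit(cache=True)
def _rhs(x: np.ndarray) -> np.ndarray:
    """(1 - x^2) * (x @ x) with a zero diagonal (diagonal of x is zero)."""
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            acc = 0.0
            for k in range(n):
                acc += x[i, k] * x[k, j]
            d[i, j] = (1.0 - x[i, j] * x[i, j]) * acc
    return d


@njit(cache=True)
def _corner_distance(x: np.ndarray) -> float:
    """max over i != j of | 1 - |x_ij| |."""
    n = x.shape[0]
    worst = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            dev = abs(1.0 - abs(x[i, j]))
            if dev > worst:
                worst = dev
    return worst


@njit(cache=True)
def _sign_stationary(x: np.ndarray) -> bool:
    """Sign pattern of x satisfies s_ij = sign(sum_k s_ik s_kj).

    Links with an exactly zero vote (possible only for even n) do not
    block: such corners are reported downstream as degenerate.
    """
    n = x.shape[0]
    s = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                s[i, j] = 1.0 if x[i, j] > 0 else -1.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            vote = 0.0
            for k in range(n):
                vote += s[i, k] * s[k, j]
            if vote * s[i, j] < 0.0:
                return False
    return True


@njit(cache=True)
def _error_norm(err: np.ndarray, x0: np.ndarray, x1: np.ndarray,
                rtol: float, atol: float) -> float:
    n = err.shape[0]
    acc = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            scale = atol + rtol * max(abs(x0[i, j]), abs(x1[i, j]))
            r = err[i, j] / scale
            acc += r * r
    return np.sqrt(acc / (n * (n - 1)))


@njit(cache=True)
def _dopri_evolve(x0: np.ndarray, corner_tol: float, t_max: float,
                  rtol: float, atol: float, max_drift: float,
                  a: np.ndarray, b: np.ndarray, e: np.ndarray,
                  c: np.ndarray):
    """Integrate to a corner.  Returns (x, t, status).

    status: 0 converged to a corner, 1 t_max reached, 2 relation drifted
    beyond 1 + max_drift (solver misconfiguration).
    """
    n = x0.shape[0]
    x = x0.copy()
    t = 0.0
    if _corner_distance(x) <= corner_tol and _sign_stationary(x):
        return x, t, 0
    k = np.zeros((7, n, n))
    h = 0.01
    k[0] = _rhs(x)
    while t < t_max:
        if t + h > t_max:
            h = t_max - t
        # six new stages; stage 0 reuses the last rhs (FSAL)
        for s in range(1, 6):
            y = x.copy()
            for q in range(s):
                if a[s, q] != 0.0:
                    y += h * a[s, q] * k[q]
            k[s] = _rhs(y)
        x_new = x.copy()
        for q in range(6):
            if b[q] != 0.0:
                x_new += h * b[q] * k[q]
        k[6] = _rhs(x_new)
        err = np.zeros((n, n))
        for q in range(7):
            if e[q] != 0.0:
                err += h * e[q] * k[q]
        enorm = _error_norm(err, x, x_new, rtol, atol)
        if enorm <= 1.0:
            t += h
            # Clip tiny floating overshoots back INSIDE the hypercube.
            # Clipping to exactly +-1 would freeze the entry forever
            # (the saturating factor vanishes); clipping just inside
            # keeps it free to escape should its triad vote flip.
            worst = 0.0
            for i in range(n):
                for j in range(n):
                    if i == j:
                        continue
                    v = abs(x_new[i, j])
                    if v > 1.0:
                        if v - 1.0 > worst:
                            worst = v - 1.0
                        inside = 1.0 - 1e-12
                        x_new[i, j] = inside if x_new[i, j] > 0 else -inside
            if worst > max_drift:
                return x_new, t, 2
            x = x_new
            if _corner_distance(x) <= corner_tol and _sign_stationary(x):
                return x, t, 0
            k[0] = _rhs(x)  # FSAL not reusable after clipping; cheap anyway
        # step-size update (order-5 controller)
        if enorm == 0.0:
            factor = 10.0
        else:
            factor = 0.9 * enorm ** (-0.2)
            if factor < 0.2:
                factor = 0.2
            elif factor > 10.0:
                factor = 10.0
        h *= factor
        if h < 1e-12:
            return x, t, 2
    return x, t, 1


def dopri_evolve(x0: np.ndarray, corner_tol: float, t_max: float,
                 rtol: float, atol: float, max_drift: float = 1e-6):
    """Python entry point for the compiled stepper."""
    return _dopri_evolve(np.ascontiguousarray(x0, dtype=np.float64),
                         corner_tol, t_max, rtol, atol, max_drift,
                         _A, _B, _E, _C)


def rhs_matrix(x: np.ndarray) -> np.ndarray:
    """Derivative matrix of the balance dynamics (public helper)."""
    return _rhs(np.ascontiguousarray(x, dtype=np.float64))
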