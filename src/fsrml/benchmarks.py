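"""Classical single-objective benchmark suite (F1-F23).

The 23 functions are the standard unimodal (F1-F7), multimodal (F8-F13) and
fixed-dimension multimodal (F14-F23) test set used throughout the swarm
optimisation literature: Sphere, Schwefel variants, Rosenbrock, Step, noisy
Quartic, Rastrigin, Ackley, Griewank, the two penalised functions, Shekel's
Foxholes, Kowalik, Six-Hump Camel, Branin, Goldstein-Price, Hartmann 3/6 and
the Shekel family.  All evaluators are vectorised: they accept a single
position of shape ``(d,)`` or a population of shape ``(n, d)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = ["BenchmarkFunction", "get_benchmark", "suite", "suite_table"]


@dataclass(frozen=True)
class BenchmarkFunction:
    """A benchmark objective with its canonical search domain.

    Attributes
    ----------
    name : str
        Identifier ``F1`` .. ``F23``.
    dimension : int
        Canonical dimensionality (30 for the scalable F1-F13).
    lower, upper : np.ndarray
        Per-dimension closed bounds, each of shape ``(dimension,)``.
    global_minimum_value : float
        Best known objective value on the domain (noise-free part for F7).
    optimum_position : np.ndarray or None
        A global minimiser, where one is known in closed form or published
        to high precision; ``None`` for the noisy Quartic.
    optimum_tolerance : float
        Absolute tolerance at which ``evaluate(optimum_position)`` matches
        ``global_minimum_value`` (loose for functions whose optima are only
        tabulated to a few decimals).
    stochastic : bool
        True for F7, whose canonical form adds uniform [0,1) noise.
    """

    name: str
    dimension: int
    lower: np.ndarray
    upper: np.ndarray
    global_minimum_value: float
    _evaluate: Callable[..., np.ndarray] = field(repr=False)
    optimum_position: Optional[np.ndarray] = None
    optimum_tolerance: float = 1e-9
    stochastic: bool = False

    def evaluate(self, x, rng: Optional[np.random.Generator] = None):
        """Evaluate at ``x`` (shape ``(d,)`` or ``(n, d)``).

        ``rng`` feeds the additive noise of the stochastic F7; it is ignored
        by the deterministic functions, and omitting it evaluates F7's
        noise-free part.
        """
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        X = np.atleast_2d(x)
        if X.shape[1] != self.dimension:
            raise ValueError(
                f"{self.name} expects dimension {self.dimension}, got {X.shape[1]}"
            )
        out = self._evaluate(X, rng) if self.stochastic else self._evaluate(X)
        out = np.asarray(out, dtype=float)
        return float(out[0]) if single else out

    def __call__(self, x, rng=None):
        return self.evaluate(x, rng=rng)


# ---------------------------------------------------------------------------
# scalable functions F1-F13 (dimension 30 by canon)
# ---------------------------------------------------------------------------

def _sphere(X):
    return np.sum(X**2, axis=1)


def _schwefel_222(X):
    a = np.abs(X)
    return np.sum(a, axis=1) + np.prod(a, axis=1)


def _schwefel_12(X):
    return np.sum(np.cumsum(X, axis=1) ** 2, axis=1)


def _schwefel_221(X):
    return np.max(np.abs(X), axis=1)


def _rosenbrock(X):
    return np.sum(
        100.0 * (X[:, 1:] - X[:, :-1] ** 2) ** 2 + (X[:, :-1] - 1.0) ** 2, axis=1
    )


def _step(X):
    return np.sum(np.floor(X + 0.5) ** 2, axis=1)


def _quartic_noise(X, rng=None):
    i = np.arange(1, X.shape[1] + 1)
    base = np.sum(i * X**4, axis=1)
    if rng is not None:
        base = base + rng.random(X.shape[0])
    return base


def _schwefel_226(X):
    return -np.sum(X * np.sin(np.sqrt(np.abs(X))), axis=1)


def _rastrigin(X):
    return np.sum(X**2 - 10.0 * np.cos(2 * np.pi * X) + 10.0, axis=1)


def _ackley(X):
    d = X.shape[1]
    return (
        -20.0 * np.exp(-0.2 * np.sqrt(np.sum(X**2, axis=1) / d))
        - np.exp(np.sum(np.cos(2 * np.pi * X), axis=1) / d)
        + 20.0
        + np.e
    )


def _griewank(X):
    i = np.sqrt(np.arange(1, X.shape[1] + 1))
    return (
        np.sum(X**2, axis=1) / 4000.0 - np.prod(np.cos(X / i), axis=1) + 1.0
    )


def _penalty_u(X, a, k, m):
    over = np.where(X > a, k * (X - a) ** m, 0.0)
    under = np.where(X < -a, k * (-X - a) ** m, 0.0)
    return np.sum(over + under, axis=1)


def _penalized_1(X):
    d = X.shape[1]
    y = 1.0 + (X + 1.0) / 4.0
    term = (
        10.0 * np.sin(np.pi * y[:, 0]) ** 2
        + np.sum(
            (y[:, :-1] - 1.0) ** 2 * (1.0 + 10.0 * np.sin(np.pi * y[:, 1:]) ** 2),
            axis=1,
        )
        + (y[:, -1] - 1.0) ** 2
    )
    return np.pi / d * term + _penalty_u(X, 10.0, 100.0, 4)


def _penalized_2(X):
    term = (
        np.sin(3 * np.pi * X[:, 0]) ** 2
        + np.sum(
            (X[:, :-1] - 1.0) ** 2 * (1.0 + np.sin(3 * np.pi * X[:, 1:]) ** 2),
            axis=1,
        )
        + (X[:, -1] - 1.0) ** 2 * (1.0 + np.sin(2 * np.pi * X[:, -1]) ** 2)
    )
    return 0.1 * term + _penalty_u(X, 5.0, 100.0, 4)


# ---------------------------------------------------------------------------
# fixed-dimension functions F14-F23
# ---------------------------------------------------------------------------

_FOXHOLES_A = np.array(
    [
        np.tile([-32.0, -16.0, 0.0, 16.0, 32.0], 5),
        np.repeat([-32.0, -16.0, 0.0, 16.0, 32.0], 5),
    ]
)  # shape (2, 25)


def _foxholes(X):
    # (n, 2, 25) differences
    diff = X[:, :, None] - _FOXHOLES_A[None, :, :]
    inner = np.arange(1, 26) + np.sum(diff**6, axis=1)
    return 1.0 / (1.0 / 500.0 + np.sum(1.0 / inner, axis=1))


_KOWALIK_A = np.array(
    [0.1957, 0.1947, 0.1735, 0.1600, 0.0844, 0.0627,
     0.0456, 0.0342, 0.0323, 0.0235, 0.0246]
)
_KOWALIK_B = 1.0 / np.array(
    [0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0]
)


def _kowalik(X):
    b = _KOWALIK_B[None, :]
    num = X[:, [0]] * (b**2 + b * X[:, [1]])
    den = b**2 + b * X[:, [2]] + X[:, [3]]
    return np.sum((_KOWALIK_A[None, :] - num / den) ** 2, axis=1)


def _six_hump_camel(X):
    x1, x2 = X[:, 0], X[:, 1]
    return (
        4 * x1**2 - 2.1 * x1**4 + x1**6 / 3.0 + x1 * x2 - 4 * x2**2 + 4 * x2**4
    )


def _branin(X):
    x1, x2 = X[:, 0], X[:, 1]
    return (
        (x2 - 5.1 / (4 * np.pi**2) * x1**2 + 5.0 / np.pi * x1 - 6.0) ** 2
        + 10.0 * (1.0 - 1.0 / (8 * np.pi)) * np.cos(x1)
        + 10.0
    )


def _goldstein_price(X):
    x1, x2 = X[:, 0], X[:, 1]
    a = 1 + (x1 + x2 + 1) ** 2 * (
        19 - 14 * x1 + 3 * x1**2 - 14 * x2 + 6 * x1 * x2 + 3 * x2**2
    )
    b = 30 + (2 * x1 - 3 * x2) ** 2 * (
        18 - 32 * x1 + 12 * x1**2 + 48 * x2 - 36 * x1 * x2 + 27 * x2**2
    )
    return a * b


_HARTMANN_ALPHA = np.array([1.0, 1.2, 3.0, 3.2])
_HARTMANN3_A = np.array(
    [[3.0, 10.0, 30.0], [0.1, 10.0, 35.0], [3.0, 10.0, 30.0], [0.1, 10.0, 35.0]]
)
_HARTMANN3_P = np.array(
    [[0.3689, 0.1170, 0.2673], [0.4699, 0.4387, 0.7470],
     [0.1091, 0.8732, 0.5547], [0.03815, 0.5743, 0.8828]]
)
_HARTMANN6_A = np.array(
    [
        [10.0, 3.0, 17.0, 3.5, 1.7, 8.0],
        [0.05, 10.0, 17.0, 0.1, 8.0, 14.0],
        [3.0, 3.5, 1.7, 10.0, 17.0, 8.0],
        [17.0, 8.0, 0.05, 10.0, 0.1, 14.0],
    ]
)
_HARTMANN6_P = 1e-4 * np.array(
    [
        [1312, 1696, 5569, 124, 8283, 5886],
        [2329, 4135, 8307, 3736, 1004, 9991],
        [2348, 1451, 3522, 2883, 3047, 6650],
        [4047, 8828, 8732, 5743, 1091, 381],
    ]
)


def _hartmann(A, P):
    def f(X):
        diff = X[:, None, :] - P[None, :, :]
        expo = np.sum(A[None, :, :] * diff**2, axis=2)
        return -np.sum(_HARTMANN_ALPHA[None, :] * np.exp(-expo), axis=1)

    return f


_SHEKEL_A = np.array(
    [
        [4.0, 4.0, 4.0, 4.0],
        [1.0, 1.0, 1.0, 1.0],
        [8.0, 8.0, 8.0, 8.0],
        [6.0, 6.0, 6.0, 6.0],
        [3.0, 7.0, 3.0, 7.0],
        [2.0, 9.0, 2.0, 9.0],
        [5.0, 5.0, 3.0, 3.0],
        [8.0, 1.0, 8.0, 1.0],
        [6.0, 2.0, 6.0, 2.0],
        [7.0, 3.6, 7.0, 3.6],
    ]
)
_SHEKEL_C = 0.1 * np.array([1, 2, 2, 4, 4, 6, 3, 7, 5, 5], dtype=float)


def _shekel(m):
    A, C = _SHEKEL_A[:m], _SHEKEL_C[:m]

    def f(X):
        diff = X[:, None, :] - A[None, :, :]
        return -np.sum(1.0 / (np.sum(diff**2, axis=2) + C[None, :]), axis=1)

    return f


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

def _make(name, dim, lo, hi, fmin, func, xopt=None, tol=1e-9, stochastic=False):
    lo = np.broadcast_to(np.asarray(lo, dtype=float), (dim,)).copy()
    hi = np.broadcast_to(np.asarray(hi, dtype=float), (dim,)).copy()
    xopt = None if xopt is None else np.asarray(xopt, dtype=float)
    return BenchmarkFunction(
        name=name,
        dimension=dim,
        lower=lo,
        upper=hi,
        global_minimum_value=fmin,
        _evaluate=func,
        optimum_position=xopt,
        optimum_tolerance=tol,
        stochastic=stochastic,
    )


_SHEKEL_XOPT = [4.00004, 4.00013, 4.00004, 4.00013]

_REGISTRY = {
    "F1": _make("F1", 30, -100, 100, 0.0, _sphere, np.zeros(30)),
    "F2": _make("F2", 30, -10, 10, 0.0, _schwefel_222, np.zeros(30)),
    "F3": _make("F3", 30, -100, 100, 0.0, _schwefel_12, np.zeros(30)),
    "F4": _make("F4", 30, -100, 100, 0.0, _schwefel_221, np.zeros(30)),
    "F5": _make("F5", 30, -30, 30, 0.0, _rosenbrock, np.ones(30)),
    "F6": _make("F6", 30, -100, 100, 0.0, _step, np.zeros(30)),
    "F7": _make("F7", 30, -1.28, 1.28, 0.0, _quartic_noise, np.zeros(30),
                stochastic=True),
    "F8": _make("F8", 30, -500, 500, -418.9828872724338 * 30, _schwefel_226,
                np.full(30, 420.968746), tol=1e-4),
    "F9": _make("F9", 30, -5.12, 5.12, 0.0, _rastrigin, np.zeros(30)),
    "F10": _make("F10", 30, -32, 32, 0.0, _ackley, np.zeros(30), tol=1e-9),
    "F11": _make("F11", 30, -600, 600, 0.0, _griewank, np.zeros(30)),
    "F12": _make("F12", 30, -50, 50, 0.0, _penalized_1, -np.ones(30)),
    "F13": _make("F13", 30, -50, 50, 0.0, _penalized_2, np.ones(30)),
    "F14": _make("F14", 2, -65.536, 65.536, 0.9980038377944498, _foxholes,
                 [-31.9783373318, -31.9783386080], tol=1e-8),
    "F15": _make("F15", 4, -5, 5, 3.0748610e-4, _kowalik,
                 [0.192833, 0.190836, 0.123117, 0.135766], tol=1e-7),
    "F16": _make("F16", 2, -5, 5, -1.0316284534898774, _six_hump_camel,
                 [0.08984201368, -0.7126564032], tol=1e-9),
    "F17": _make("F17", 2, [-5, 0], [10, 15], 0.39788735772973816, _branin,
                 [np.pi, 2.275], tol=1e-9),
    "F18": _make("F18", 2, -2, 2, 3.0, _goldstein_price, [0.0, -1.0]),
    "F19": _make("F19", 3, 0, 1, -3.86278214782076,
                 _hartmann(_HARTMANN3_A, _HARTMANN3_P),
                 [0.1146143, 0.5556488, 0.8525470], tol=1e-7),
    "F20": _make("F20", 6, 0, 1, -3.3223680114155156,
                 _hartmann(_HARTMANN6_A, _HARTMANN6_P),
                 [0.20169, 0.150011, 0.476874, 0.275332, 0.311652, 0.6573],
                 tol=1e-5),
    "F21": _make("F21", 4, 0, 10, -10.153199679058231, _shekel(5),
                 [4.0000371541, 4.0001332771, 4.0000371516, 4.0001332759],
                 tol=1e-8),
    "F22": _make("F22", 4, 0, 10, -10.402940566818663, _shekel(7),
                 [4.0005729149, 4.0006893664, 3.9994897086, 3.9996061574],
                 tol=1e-8),
    "F23": _make("F23", 4, 0, 10, -10.536409816692046, _shekel(10),
                 [4.0007465306, 4.0005929326, 3.9996633982, 3.9995098006],
                 tol=1e-8),
}


def get_benchmark(name: str) -> BenchmarkFunction:
    """Look up a benchmark function by its ``F1`` .. ``F23`` identifier."""
    try:
        return _REGISTRY[name]
    except KeyError:
        valid = ", ".join(_REGISTRY)
        raise KeyError(f"unknown benchmark {name!r}; valid names: {valid}") from None


def suite() -> list[BenchmarkFunction]:
    """All 23 functions in F1..F23 order."""
    return [_REGISTRY[f"F{i}"] for i in range(1, 24)]


def suite_table():
    """Suite metadata (name, dimension, bounds, known minimum) as a DataFrame."""
    import pandas as pd

    rows = [
        {
            "name": f.name,
            "dimension": f.dimension,
            "lower": f.lower[0] if np.all(f.lower == f.lower[0]) else list(f.lower),
            "upper": f.upper[0] if np.all(f.upper == f.upper[0]) else list(f.upper),
            "global_minimum": f.global_minimum_value,
        }
        for f in suite()
    ]
    return pd.DataFrame(rows)
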