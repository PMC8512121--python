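"""Classic analytic benchmark functions for desk-scale optimizer validation.

The registry mirrors the function families of the CEC2019 "100-digit"
suite in their classic textbook forms — unshifted, unrotated, evaluating
from plain formulas with no data files — so a run here is reproducible
anywhere.  The three fixed-dimension problems (Chebyshev polynomial fitting,
inverse Hilbert matrix, Lennard-Jones cluster) are identical to their suite
counterparts up to the suite's +1 reporting offset; the seven rotated suite
functions are represented by their underlying classics on the same boxes.

A separate optional adapter (:mod:`hawkopt.cec2019`) loads the official
shifted/rotated definitions from externally supplied data files; the two are
deliberately kept apart so classic-form results are never confused with
suite results.
"""

from __future__ import annotations

import numpy as np

from .problems import BoxProblem

__all__ = ["make_builtin", "builtin_names", "REGISTRY"]


# -- fixed-dimension classics -------------------------------------------------

def chebyshev(x: np.ndarray) -> float:
    """Storn's Chebyshev polynomial fitting problem (degree D-1 coefficients).

    Penalizes the polynomial p(y) = sum_j x_j * y^(D-1-j) for leaving the
    band [-1, 1] on [-1, 1] (sampled at 32*D+1 points) and for falling below
    T_{D-1}(1.2) at y = +/-1.2.  Global minimum 0 at the coefficients of the
    Chebyshev polynomial T_{D-1}.
    """
    x = np.asarray(x, dtype=float)
    d = x.shape[0]
    sample = 32 * d
    # T_{d-1} evaluated at 1.2 via the three-term recurrence
    a, b = 1.0, 1.2
    for _ in range(d - 2):
        a, b = b, 2.4 * b - a
    t_edge = b
    y = np.linspace(-1.0, 1.0, sample + 1)
    p = np.polyval(x, y)
    out = np.abs(p) > 1.0
    total = float(np.sum((1.0 - np.abs(p[out])) ** 2))
    for edge in (-1.2, 1.2):
        pe = np.polyval(x, edge)
        if pe < t_edge:
            total += pe * pe
    return total


def chebyshev_optimum_point(d: int = 9) -> np.ndarray:
    """Coefficients of T_{d-1}, the global minimizer of :func:`chebyshev`."""
    return np.polynomial.chebyshev.cheb2poly(np.eye(d)[-1])[::-1]


def inverse_hilbert(x: np.ndarray) -> float:
    """Inverse Hilbert matrix problem: ``sum |H Z - I|`` with Z = x reshaped n x n.

    Global minimum 0 at Z equal to the exact inverse of the Hilbert matrix.
    """
    x = np.asarray(x, dtype=float)
    n = int(round(np.sqrt(x.shape[0])))
    if n * n != x.shape[0]:
        raise ValueError("dimension must be a perfect square")
    z = x.reshape(n, n)
    i, j = np.indices((n, n))
    h = 1.0 / (i + j + 1.0)
    return float(np.abs(h @ z - np.eye(n)).sum())


def inverse_hilbert_optimum_point(d: int = 16) -> np.ndarray:
    from scipy.linalg import invhilbert

    n = int(round(np.sqrt(d)))
    return invhilbert(n, exact=True).astype(float).ravel()


def lennard_jones(x: np.ndarray) -> float:
    """Pairwise 12-6 Lennard-Jones potential of a D/3-atom cluster.

    Pair energy ``r^-12 - 2*r^-6`` (minimum -1 at r = 1); the 6-atom global
    minimum is the octahedron at -12.7120622568.  Near-coincident atoms are
    assigned a large penalty instead of overflowing.
    """
    x = np.asarray(x, dtype=float)
    atoms = x.reshape(-1, 3)
    diff = atoms[:, None, :] - atoms[None, :, :]
    r2 = np.einsum("ijk,ijk->ij", diff, diff)
    iu = np.triu_indices(atoms.shape[0], k=1)
    r6 = r2[iu] ** 3
    total = 0.0
    for v in r6:
        if v > 1e-10:
            total += 1.0 / (v * v) - 2.0 / v
        else:
            total += 1e20
    return float(total)


#: 6-atom octahedral minimum of the 12-6 potential above, exact rational value.
LJ6_MINIMUM = -39204.0 / 3084.0


def lj6_optimum_point() -> np.ndarray:
    """Octahedron vertices at the optimal radius for the 6-atom cluster."""
    # pair-energy balance gives a^6 = 2*(771/4096)/(99/32)
    a = (2.0 * (771.0 / 4096.0) / (99.0 / 32.0)) ** (1.0 / 6.0)
    pts = np.array(
        [[a, 0, 0], [-a, 0, 0], [0, a, 0], [0, -a, 0], [0, 0, a], [0, 0, -a]]
    )
    return pts.ravel()


# -- scalable classics --------------------------------------------------------

def rastrigin(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.sum(x * x - 10.0 * np.cos(2.0 * np.pi * x) + 10.0))


def griewank(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    i = np.arange(1, x.shape[0] + 1)
    return float(np.sum(x * x) / 4000.0 - np.prod(np.cos(x / np.sqrt(i))) + 1.0)


def weierstrass(x: np.ndarray, a: float = 0.5, b: float = 3.0, kmax: int = 20) -> float:
    x = np.asarray(x, dtype=float)
    k = np.arange(kmax + 1)
    ak = a ** k
    bk = b ** k
    inner = np.sum(ak * np.cos(2.0 * np.pi * np.outer(x + 0.5, bk)), axis=1)
    shift = x.shape[0] * np.sum(ak * np.cos(np.pi * bk))
    return float(np.sum(inner) - shift)


_SCHWEFEL_PEAK = 418.9828872724338  # max of z*sin(sqrt(z)) on [0, 500]
_SCHWEFEL_SHIFT = 420.9687462275036


def modified_schwefel(x: np.ndarray) -> float:
    """Modified Schwefel function with out-of-range fold-back terms.

    Classic global minimum 0 at x = 0 (i.e. z at the sin-peak argument).
    """
    x = np.asarray(x, dtype=float)
    z = x + _SCHWEFEL_SHIFT
    total = 0.0
    for zi in z:
        if abs(zi) <= 500.0:
            g = zi * np.sin(np.sqrt(abs(zi)))
        elif zi > 500.0:
            zm = 500.0 - zi % 500.0
            g = zm * np.sin(np.sqrt(abs(zm))) - (zi - 500.0) ** 2 / (10000.0 * x.shape[0])
        else:
            zm = zi % 500.0 - 500.0
            g = zm * np.sin(np.sqrt(abs(zm))) - (zi + 500.0) ** 2 / (10000.0 * x.shape[0])
        total += g
    return float(_SCHWEFEL_PEAK * x.shape[0] - total)


def expanded_schaffer_f6(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    xi = x
    xj = np.roll(x, -1)
    s = xi * xi + xj * xj
    g = 0.5 + (np.sin(np.sqrt(s)) ** 2 - 0.5) / (1.0 + 0.001 * s) ** 2
    return float(np.sum(g))


def happy_cat(x: np.ndarray, alpha: float = 0.125) -> float:
    x = np.asarray(x, dtype=float)
    d = x.shape[0]
    r2 = float(np.sum(x * x))
    return float(
        abs(r2 - d) ** (2 * alpha) + (0.5 * r2 + np.sum(x)) / d + 0.5
    )


def ackley(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    d = x.shape[0]
    return float(
        -20.0 * np.exp(-0.2 * np.sqrt(np.sum(x * x) / d))
        - np.exp(np.sum(np.cos(2.0 * np.pi * x)) / d)
        + 20.0
        + np.e
    )


def sphere(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.sum(x * x))


# name -> (objective, default D, fixed-D?, (lb, ub), known optimum, optimum point)
REGISTRY = {
    "chebyshev": (chebyshev, 9, True, (-8192.0, 8192.0), 0.0, chebyshev_optimum_point),
    "inverse_hilbert": (
        inverse_hilbert, 16, True, (-16384.0, 16384.0), 0.0, inverse_hilbert_optimum_point,
    ),
    "lennard_jones": (lennard_jones, 18, True, (-4.0, 4.0), LJ6_MINIMUM, lj6_optimum_point),
    "rastrigin": (rastrigin, 10, False, (-100.0, 100.0), 0.0, None),
    "griewank": (griewank, 10, False, (-100.0, 100.0), 0.0, None),
    "weierstrass": (weierstrass, 10, False, (-100.0, 100.0), 0.0, None),
    "modified_schwefel": (modified_schwefel, 10, False, (-100.0, 100.0), 0.0, None),
    "expanded_schaffer_f6": (expanded_schaffer_f6, 10, False, (-100.0, 100.0), 0.0, None),
    "happy_cat": (happy_cat, 10, False, (-100.0, 100.0), 0.0, None),
    "ackley": (ackley, 10, False, (-100.0, 100.0), 0.0, None),
    "sphere": (sphere, 10, False, (-100.0, 100.0), 0.0, None),
}


def builtin_names() -> list[str]:
    return sorted(REGISTRY)


def make_builtin(name: str, d: int | None = None) -> BoxProblem:
    """Build a registered classic benchmark as a :class:`BoxProblem`.

    ``d`` overrides the default dimension for the scalable functions; the
    fixed-dimension problems reject a mismatching request.
    """
    if name not in REGISTRY:
        raise KeyError(
            f"unknown benchmark {name!r}; available: {', '.join(builtin_names())}"
        )
    fn, d_default, fixed, (lb, ub), opt, _ = REGISTRY[name]
    if d is None:
        d = d_default
    elif fixed and d != d_default:
        raise ValueError(f"{name} is defined only for D={d_default}")
    return BoxProblem(
        name=name,
        dimension=d,
        lower=np.full(d, lb),
        upper=np.full(d, ub),
        objective=fn,
        known_optimum=opt,
    )
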