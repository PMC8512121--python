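"""Optional adapter for the official CEC2019 "100-digit" suite definitions.

The suite's functions 4-10 are shifted and rotated: their shift vectors and
rotation matrices are distributed with the official suite as plain-text
files (``shift_data_<i>.txt`` and ``M_<i>_D<D>.txt``) and are *not* bundled
here.  Point :func:`load_cec2019` at a directory containing those files to
obtain the ten suite problems; without the files it raises an explicit error
naming what is missing — it never silently substitutes the classic forms.

Functions 1-3 are analytic (no data files) and identical to the classic
forms in :mod:`hawkopt.benchmarks` plus the suite's +1 reporting offset.
Every suite function reports ``F(x*) = 1`` in the official normalization,
except that widely used distributions of function 3 evaluate to ~12.7 at
their distributed optimum; the adapter reports whatever the definitions
return and takes no position on the discrepancy.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .benchmarks import (
    ackley,
    chebyshev,
    expanded_schaffer_f6,
    griewank,
    happy_cat,
    inverse_hilbert,
    lennard_jones,
    modified_schwefel,
    rastrigin,
    weierstrass,
)
from .problems import BoxProblem

__all__ = ["load_cec2019", "CEC2019_SPECS"]

# number -> (kernel, D, |bound|, shrink rate applied before rotation)
CEC2019_SPECS = {
    1: (chebyshev, 9, 8192.0, None),
    2: (inverse_hilbert, 16, 16384.0, None),
    3: (lennard_jones, 18, 4.0, None),
    4: (rastrigin, 10, 100.0, 5.12 / 100.0),
    5: (griewank, 10, 100.0, 600.0 / 100.0),
    6: (weierstrass, 10, 100.0, 0.5 / 100.0),
    7: (modified_schwefel, 10, 100.0, 1000.0 / 100.0),
    8: (expanded_schaffer_f6, 10, 100.0, 1.0),
    9: (happy_cat, 10, 100.0, 5.0 / 100.0),
    10: (ackley, 10, 100.0, 1.0),
}


def _load_vector(path: Path, d: int) -> np.ndarray:
    data = np.loadtxt(path).ravel()
    return data[:d]


def _load_matrix(path: Path, d: int) -> np.ndarray:
    data = np.loadtxt(path)
    return data.reshape(d, d)


def load_cec2019(data_dir: str | Path) -> list[BoxProblem]:
    """Load all ten CEC2019 problems from an official data directory.

    Raises ``FileNotFoundError`` listing every missing shift/rotation file
    before building anything, so a partial directory fails loudly.
    """
    data_dir = Path(data_dir)
    required: list[Path] = []
    for i, (_, d, _, shrink) in CEC2019_SPECS.items():
        if shrink is None:
            continue
        required.append(data_dir / f"shift_data_{i}.txt")
        required.append(data_dir / f"M_{i}_D{d}.txt")
    missing = [str(p) for p in required if not p.exists()]
    if missing:
        raise FileNotFoundError(
            "CEC2019 definition data not found; the official suite "
            "distribution must provide: " + ", ".join(missing)
        )

    problems: list[BoxProblem] = []
    for i, (kernel, d, bound, shrink) in CEC2019_SPECS.items():
        if shrink is None:
            def objective(x, _kernel=kernel):
                return _kernel(x) + 1.0
        else:
            shift = _load_vector(data_dir / f"shift_data_{i}.txt", d)
            rot = _load_matrix(data_dir / f"M_{i}_D{d}.txt", d)

            def objective(x, _kernel=kernel, _s=shift, _m=rot, _sh=shrink):
                z = _m @ ((np.asarray(x, dtype=float) - _s) * _sh)
                return _kernel(z) + 1.0

        problems.append(
            BoxProblem(
                name=f"cec2019-f{i:02d}",
                dimension=d,
                lower=np.full(d, -bound),
                upper=np.full(d, bound),
                objective=objective,
                known_optimum=1.0,
            )
        )
    return problems
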