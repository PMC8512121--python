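"""Nonparametric comparison of optimizers over a set of problems.

Works on an *algorithms x problems* table of mean final objective values
(lower is better by default).  The battery is the standard one for
metaheuristics papers:

* **Friedman test**: rank algorithms within each problem (ties averaged),
  average the ranks, and form the chi-square statistic

  ``chi2_F = 12 / (n k (k+1)) * sum_j Rsum_j^2  -  3 n (k+1)``

  with n problems and k algorithms.  The classical, tie-uncorrected form is
  the default (a tie-corrected variant is available behind a flag).
* **Iman-Davenport refinement**: ``F_ID = (n-1) chi2_F / (n (k-1) - chi2_F)``,
  compared against the F distribution with (k-1, (k-1)(n-1)) degrees of
  freedom — less conservative than the raw chi-square.
* **Holm step-down procedure** against a control algorithm: for each
  competitor, ``z = (Rbar_j - Rbar_control) / sqrt(k (k+1) / (6 n))`` with a
  one-sided upper-tail normal p-value; p-values are sorted ascending and the
  i-th is compared with ``alpha / (K - i)`` (K comparisons, i = 0, 1, ...),
  rejecting sequentially until the first failure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ResultTable",
    "FriedmanResult",
    "HolmRow",
    "friedman",
    "iman_davenport",
    "holm_stepdown",
]


@dataclass
class ResultTable:
    """Mean (and optional std) final objective values, problems x algorithms."""

    mean: pd.DataFrame
    std: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.mean.shape[0] < 2 or self.mean.shape[1] < 2:
            raise ValueError("need at least 2 problems and 2 algorithms")
        if not np.isfinite(self.mean.to_numpy(dtype=float)).all():
            raise ValueError("result table contains non-finite cells")

    @property
    def algorithms(self) -> list[str]:
        return list(self.mean.columns)

    @property
    def problems(self) -> list[str]:
        return list(self.mean.index)

    @classmethod
    def from_csv(cls, means_path, std_path=None) -> "ResultTable":
        """Read a problems-as-rows, algorithms-as-columns CSV (first column index)."""
        mean = pd.read_csv(means_path, index_col=0)
        std = pd.read_csv(std_path, index_col=0) if std_path is not None else None
        return cls(mean=mean, std=std)


@dataclass
class FriedmanResult:
    ranks: pd.DataFrame
    average_ranks: pd.Series
    chi_square: float
    p_value: float
    n: int
    k: int
    tie_corrected: bool = False

    def critical_value(self, alpha: float = 0.05) -> float:
        """Chi-square critical value at k-1 degrees of freedom."""
        return float(stats.chi2.ppf(1.0 - alpha, self.k - 1))


def friedman(
    table: ResultTable, maximize: bool = False, tie_correction: bool = False
) -> FriedmanResult:
    """Friedman two-way analysis by ranks over the mean-result table.

    Lower values rank better under minimization (the default); set
    ``maximize=True`` for score-like tables.
    """
    values = table.mean.to_numpy(dtype=float)
    if maximize:
        values = -values
    n, k = values.shape
    ranks = np.vstack([stats.rankdata(row, method="average") for row in values])
    avg = ranks.mean(axis=0)
    rank_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * float(np.sum(rank_sums**2)) - 3.0 * n * (k + 1)
    if tie_correction:
        correction = 0.0
        for row in ranks:
            _, counts = np.unique(row, return_counts=True)
            correction += float(np.sum(counts**3 - counts))
        denom = 1.0 - correction / (n * k * (k * k - 1))
        if denom <= 0:
            raise ValueError("all rows fully tied; Friedman statistic undefined")
        chi2 /= denom
    p = float(stats.chi2.sf(chi2, k - 1))
    return FriedmanResult(
        ranks=pd.DataFrame(ranks, index=table.problems, columns=table.algorithms),
        average_ranks=pd.Series(avg, index=table.algorithms),
        chi_square=float(chi2),
        p_value=p,
        n=n,
        k=k,
        tie_corrected=tie_correction,
    )


def iman_davenport(fr: FriedmanResult, alpha: float = 0.05) -> tuple[float, float]:
    """Iman-Davenport F statistic and its critical value at ``alpha``.

    Raises when the chi-square saturates the rank variance (denominator <= 0).
    """
    n, k = fr.n, fr.k
    denom = n * (k - 1) - fr.chi_square
    if denom <= 0:
        raise ValueError(
            "Friedman chi-square too large for n, k: Iman-Davenport undefined"
        )
    f_id = (n - 1) * fr.chi_square / denom
    crit = float(stats.f.ppf(1.0 - alpha, k - 1, (k - 1) * (n - 1)))
    return float(f_id), crit


@dataclass
class HolmRow:
    comparison: str
    z: float
    p_value: float
    index: int
    thresholds: dict = field(default_factory=dict)
    reject: dict = field(default_factory=dict)


def holm_stepdown(
    fr: FriedmanResult,
    control: str,
    alphas: tuple[float, ...] = (0.05, 0.1),
    k_comparisons: int | None = None,
) -> list[HolmRow]:
    """Holm step-down of every algorithm against ``control``.

    Rows are sorted ascending by p-value and indexed i = 0, 1, ...; row i is
    tested at ``alpha / (K - i)`` where K defaults to the number of
    comparisons (k - 1).  Rejection stops at the first non-significant row.
    """
    if control not in fr.average_ranks.index:
        raise KeyError(f"control algorithm {control!r} not in the table")
    se = np.sqrt(fr.k * (fr.k + 1) / (6.0 * fr.n))
    r_control = fr.average_ranks[control]
    rows = []
    for name, r in fr.average_ranks.items():
        if name == control:
            continue
        z = (r - r_control) / se
        rows.append((name, float(z), float(stats.norm.sf(z))))
    rows.sort(key=lambda t: t[2])
    kk = (fr.k - 1) if k_comparisons is None else k_comparisons
    out: list[HolmRow] = []
    blocked = {alpha: False for alpha in alphas}
    for i, (name, z, p) in enumerate(rows):
        thresholds = {alpha: alpha / (kk - i) for alpha in alphas}
        reject = {}
        for alpha in alphas:
            ok = (not blocked[alpha]) and p <= thresholds[alpha]
            reject[alpha] = ok
            if not ok:
                blocked[alpha] = True
        out.append(
            HolmRow(
                comparison=f"{control} vs. {name}",
                z=z,
                p_value=p,
                index=i,
                thresholds=thresholds,
                reject=reject,
            )
        )
    return out
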