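"""Pearson correlations of the PD parameters and Fisher r-to-z comparisons.

The D-U correlation is computed overall and within condition cells; pairs of
independent cells are compared with the Fisher transform, z =
(atanh|r1| - atanh|r2|) / sqrt(1/(n1-3) + 1/(n2-3)).  Magnitudes are
compared (sign-free reporting): z is positive when the first sample's
correlation is the stronger one.  The tail convention is explicit per call
and defaults to two-sided.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats

TWO_SIDED = "two_sided"
ONE_SIDED = "one_sided"


@dataclass(frozen=True)
class CorrResult:
    r: float
    n: int
    t: float
    p: float


@dataclass(frozen=True)
class CorrComparison:
    r1: float
    n1: int
    r2: float
    n2: int
    z: float
    p: float
    tail: str


def pearson(x, y) -> CorrResult:
    """Sample Pearson correlation with its two-sided t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    if abs(r) < 1.0:
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    else:
        t = float("inf") if r > 0 else float("-inf")
    return CorrResult(r=r, n=n, t=float(t), p=float(res.pvalue))


def _tail_p(z: float, tail: str) -> float:
    if tail == TWO_SIDED:
        return float(2.0 * stats.norm.sf(abs(z)))
    if tail == ONE_SIDED:
        return float(stats.norm.sf(z))
    raise ValueError(f"unknown tail {tail!r}")


def fisher_compare(
    r1: float, n1: int, r2: float, n2: int, tail: str = TWO_SIDED
) -> CorrComparison:
    """Independent-samples comparison of two correlations' magnitudes.

    Swapping the two samples negates z.  For the one-sided test the
    alternative is |rho1| > |rho2|.
    """
    for r in (r1, r2):
        if not abs(r) < 1:
            raise ValueError("correlations must satisfy |r| < 1")
    for n in (n1, n2):
        if n <= 3:
            raise ValueError("each sample needs n > 3")
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = float((np.arctanh(abs(r1)) - np.arctanh(abs(r2))) / se)
    return CorrComparison(r1=r1, n1=n1, r2=r2, n2=n2, z=z, p=_tail_p(z, tail), tail=tail)


def pairwise_condition_comparisons(
    cell_correlations: dict, cell_n: dict, tail: str = TWO_SIDED
) -> tuple[list[dict], float, float]:
    """All unordered pairwise Fisher comparisons across condition cells.

    ``cell_correlations`` maps cell labels to r, ``cell_n`` maps the same
    labels to group sizes.  Within each pair the cell with the larger |r| is
    taken first, so every reported z is nonnegative.  Returns the comparison
    table plus the maximum |z| and minimum p.
    """
    cells = sorted(cell_correlations)
    if len(cells) < 2:
        raise ValueError("need at least 2 cells")
    rows = []
    for a, b in itertools.combinations(cells, 2):
        first, second = (a, b) if abs(cell_correlations[a]) >= abs(
            cell_correlations[b]
        ) else (b, a)
        cmp = fisher_compare(
            cell_correlations[first], cell_n[first],
            cell_correlations[second], cell_n[second],
            tail=tail,
        )
        rows.append(
            {
                "cell_1": str(first),
                "cell_2": str(second),
                "r1": cmp.r1,
                "n1": cmp.n1,
                "r2": cmp.r2,
                "n2": cmp.n2,
                "z": cmp.z,
                "p": cmp.p,
                "tail": tail,
            }
        )
    max_abs_z = max(abs(row["z"]) for row in rows)
    min_p = min(row["p"] for row in rows)
    return rows, float(max_abs_z), float(min_p)
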