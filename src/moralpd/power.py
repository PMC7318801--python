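"""Noncentral-F sensitivity analysis for the repeated-measures design.

The study sized its samples with a sensitivity analysis for the
within-between interaction of a 2 (within: parameter type) x 2 (between:
condition) repeated-measures ANOVA.  Under the G*Power convention for this
test family the noncentrality parameter is

    lambda = f^2 * N * m / (1 - rho)

with f^2 the Cohen effect size (partial eta^2 = f^2 / (1 + f^2)), N the
total sample size, m the number of repeated measures and rho their
correlation; the test statistic is F(df1, df2, lambda) with
df1 = (g - 1)(m - 1) and df2 = (N - g)(m - 1).  An alternative "spss"
convention, in which the effect size already absorbs the m/(1 - rho)
factor so that lambda = f^2 * N, is exposed because published analyses do
not always say which one was used.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import optimize, stats


@dataclass(frozen=True)
class SensitivitySpec:
    """Design constants of the sensitivity analysis."""

    n_total: int
    n_groups: int = 2
    n_measures: int = 2
    rho: float = -0.45
    alpha: float = 0.05
    power: float = 0.80
    convention: str = "gpower"  # "gpower" | "spss"

    def __post_init__(self):
        if self.n_total <= self.n_groups:
            raise ValueError("N must exceed the number of groups")
        if self.n_measures < 2:
            raise ValueError("need at least 2 repeated measures")
        if not (-1.0 < self.rho < 1.0):
            raise ValueError("rho must lie in (-1, 1)")
        if not (0.0 < self.alpha < 1.0 and 0.0 < self.power < 1.0):
            raise ValueError("alpha and power must lie in (0, 1)")
        if self.convention not in ("gpower", "spss"):
            raise ValueError(f"unknown convention {self.convention!r}")

    @property
    def df1(self) -> int:
        return (self.n_groups - 1) * (self.n_measures - 1)

    @property
    def df2(self) -> int:
        return (self.n_total - self.n_groups) * (self.n_measures - 1)

    def noncentrality(self, f2: float) -> float:
        if self.convention == "gpower":
            return f2 * self.n_total * self.n_measures / (1.0 - self.rho)
        return f2 * self.n_total


@dataclass(frozen=True)
class PowerResult:
    f2: float
    partial_eta2: float
    noncentrality: float
    critical_f: float
    power: float
    df1: int
    df2: int


def power_from_effect(spec: SensitivitySpec, partial_eta2: float) -> PowerResult:
    """Achieved power of the within-between interaction test at a given
    partial eta^2: upper-tail noncentral-F mass beyond the central critical
    value at alpha."""
    if not (0.0 < partial_eta2 < 1.0):
        raise ValueError("partial eta^2 must lie in (0, 1)")
    f2 = partial_eta2 / (1.0 - partial_eta2)
    lam = spec.noncentrality(f2)
    fcrit = float(stats.f.ppf(1.0 - spec.alpha, spec.df1, spec.df2))
    power = float(stats.ncf.sf(fcrit, spec.df1, spec.df2, lam))
    return PowerResult(
        f2=f2, partial_eta2=partial_eta2, noncentrality=lam,
        critical_f=fcrit, power=power, df1=spec.df1, df2=spec.df2,
    )


def sensitivity_effect(spec: SensitivitySpec, tol: float = 1e-6) -> PowerResult:
    """Minimal detectable partial eta^2 at the spec's alpha and target power.

    Root-finds the effect size whose achieved power equals the target
    (inverse-consistent with :func:`power_from_effect` to within ``tol``).
    """
    def gap(eta2):
        return power_from_effect(spec, eta2).power - spec.power

    lo, hi = 1e-10, 1.0 - 1e-10
    if gap(lo) > 0 or gap(hi) < 0:
        raise RuntimeError("target power not bracketed by eta^2 in (0, 1)")
    eta2 = optimize.brentq(gap, lo, hi, xtol=1e-14, rtol=8.9e-16)
    result = power_from_effect(spec, eta2)
    if abs(result.power - spec.power) > tol:
        raise RuntimeError("sensitivity search did not reach the target power")
    return result
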