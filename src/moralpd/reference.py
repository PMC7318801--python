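"""Published summary statistics used as simulation targets and test inputs.

The three experiments this package models did not deposit trial-level data,
but their condition-cell summaries (means and standard deviations of the PD
Deontology parameter D, the PD Utilitarianism parameter U, the conventional
measure, and the within-cell D-U Pearson correlations) are public.  The
synthetic-cohort generator uses them as calibration targets, and the
correlation-comparison routines use the printed correlations and group sizes
as direct inputs.

Conditions are keyed ``(instrumentality, personal_force)`` with levels
``means``/``side_effect`` and ``personal``/``impersonal``.
"""

from __future__ import annotations

from dataclasses import dataclass

MEANS = "means"
SIDE_EFFECT = "side_effect"
PERSONAL = "personal"
IMPERSONAL = "impersonal"

Condition = tuple[str, str]


@dataclass(frozen=True)
class CellTargets:
    """Per-condition targets: mean/SD of D and U, plus the conventional measure mean."""

    d_mean: float
    d_sd: float
    u_mean: float
    u_sd: float
    conventional_mean: float | None = None


#: Condition-cell summaries for the three experiments.  Experiment 1
#: manipulated instrumentality only, with personal force held at "personal".
CELL_TARGETS: dict[int, dict[Condition, CellTargets]] = {
    1: {
        (SIDE_EFFECT, PERSONAL): CellTargets(0.62, 0.27, 0.55, 0.20, 0.71),
        (MEANS, PERSONAL): CellTargets(0.80, 0.26, 0.28, 0.22, 0.39),
    },
    2: {
        (SIDE_EFFECT, IMPERSONAL): CellTargets(0.47, 0.28, 0.50, 0.21, 0.73),
        (MEANS, IMPERSONAL): CellTargets(0.71, 0.22, 0.23, 0.14, 0.44),
        (SIDE_EFFECT, PERSONAL): CellTargets(0.67, 0.25, 0.35, 0.25, 0.55),
        (MEANS, PERSONAL): CellTargets(0.79, 0.22, 0.28, 0.19, 0.41),
    },
    3: {
        (SIDE_EFFECT, IMPERSONAL): CellTargets(0.42, 0.28, 0.50, 0.24, 0.78),
        (MEANS, IMPERSONAL): CellTargets(0.56, 0.27, 0.25, 0.21, 0.56),
        (SIDE_EFFECT, PERSONAL): CellTargets(0.55, 0.30, 0.42, 0.25, 0.66),
        (MEANS, PERSONAL): CellTargets(0.76, 0.22, 0.25, 0.20, 0.41),
    },
}

#: Within-cell Pearson correlations between the D and U parameters.
CELL_CORRELATIONS: dict[int, dict[Condition, float]] = {
    1: {
        (SIDE_EFFECT, PERSONAL): -0.20,
        (MEANS, PERSONAL): -0.48,
    },
    2: {
        (SIDE_EFFECT, IMPERSONAL): -0.20,
        (MEANS, IMPERSONAL): -0.11,
        (SIDE_EFFECT, PERSONAL): -0.06,
        (MEANS, PERSONAL): -0.37,
    },
    3: {
        (SIDE_EFFECT, IMPERSONAL): -0.16,
        (MEANS, IMPERSONAL): -0.24,
        (SIDE_EFFECT, PERSONAL): -0.24,
        (MEANS, PERSONAL): -0.45,
    },
}

#: Analysed sample sizes per condition cell.  Per-cell splits were not printed
#: for experiments 1 and 2; near-equal splits of the analysed totals (61 and
#: 88) are assumed.  Experiment 3 reported N = 75 per condition.
CELL_N: dict[int, dict[Condition, int]] = {
    1: {
        (SIDE_EFFECT, PERSONAL): 31,
        (MEANS, PERSONAL): 30,
    },
    2: {
        (SIDE_EFFECT, IMPERSONAL): 22,
        (MEANS, IMPERSONAL): 22,
        (SIDE_EFFECT, PERSONAL): 22,
        (MEANS, PERSONAL): 22,
    },
    3: {
        (SIDE_EFFECT, IMPERSONAL): 75,
        (MEANS, IMPERSONAL): 75,
        (SIDE_EFFECT, PERSONAL): 75,
        (MEANS, PERSONAL): 75,
    },
}

#: Proportion of female / male / other participants in each experiment.
SEX_PROPORTIONS: dict[int, dict[str, float]] = {
    1: {"female": 50 / 61, "male": 11 / 61, "other": 0.0},
    2: {"female": 68 / 90, "male": 22 / 90, "other": 0.0},
    3: {"female": 228 / 300, "male": 69 / 300, "other": 3 / 300},
}


def conditions(experiment: int) -> list[Condition]:
    """Condition cells of an experiment, in a fixed canonical order."""
    return list(CELL_TARGETS[experiment].keys())
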