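"""Synthetic trial-level cohorts with the structure the analysis assumes.

No raw data were deposited for the experiments this package models, so every
downstream stage is exercised on simulated cohorts.  Participants carry
latent (D, U) inclinations drawn from logit-normal distributions calibrated
so that each condition cell's sample means and SDs match the published cell
summaries; their trial responses are Bernoulli draws from the processing
tree; total processing times are lognormal; and exact-duplicate entries and
extreme-time participants can be injected with ground-truth labels so the
exclusion rules can be tested against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numpy.polynomial.hermite_e import hermegauss
from scipy import optimize, special

from . import reference
from .battery import PresentationOrder, freeze_orders, standard_battery
from .pd_core import tree_probabilities

_GH_NODES, _GH_WEIGHTS = hermegauss(63)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


@dataclass(frozen=True)
class CohortSpec:
    """Generator settings for one synthetic cohort.

    ``cells`` maps (instrumentality, personal_force) to target mean/SD of D
    and U; defaults come from the published condition-cell summaries via
    :meth:`from_experiment`.  ``rho_du`` is an optional latent correlation
    between the logit-scale D and U draws (0 = independent).  Times are
    lognormal: ``time_log_mean``/``time_log_sd`` are the mean and SD of
    log(total processing time in seconds); the defaults put the median near
    25 minutes, a typical duration for a 20-dilemma session.
    """

    cells: dict = field(default_factory=dict)
    n_per_cell: dict = field(default_factory=dict)
    sex_probs: dict = field(
        default_factory=lambda: {"female": 0.76, "male": 0.23, "other": 0.01}
    )
    rho_du: float = 0.0
    time_log_mean: float = float(np.log(1500.0))
    time_log_sd: float = 0.5
    duplicate_rate: float = 0.0
    outlier_rate: float = 0.0
    seed: int = 0

    @classmethod
    def from_experiment(
        cls, experiment: int, n_per_cell: int | None = None, seed: int = 0, **kw
    ) -> "CohortSpec":
        cells = {
            cond: (t.d_mean, t.d_sd, t.u_mean, t.u_sd)
            for cond, t in reference.CELL_TARGETS[experiment].items()
        }
        if n_per_cell is None:
            n = dict(reference.CELL_N[experiment])
        else:
            n = {cond: int(n_per_cell) for cond in cells}
        sex = dict(reference.SEX_PROPORTIONS[experiment])
        return cls(cells=cells, n_per_cell=n, sex_probs=sex, seed=seed, **kw)

    def with_(self, **kw) -> "CohortSpec":
        return replace(self, **kw)


def _logit_normal_moments(mu: float, sigma: float) -> tuple[float, float]:
    """Mean and SD of expit(mu + sigma * Z) by Gauss-Hermite quadrature."""
    p = special.expit(mu + sigma * _GH_NODES)
    m = float(_GH_WEIGHTS @ p)
    v = float(_GH_WEIGHTS @ (p * p)) - m * m
    return m, float(np.sqrt(max(v, 0.0)))


def calibrate_logit_normal(target_mean: float, target_sd: float) -> tuple[float, float]:
    """Find (mu, sigma) such that expit(mu + sigma*Z) has the target mean/SD.

    ``target_sd = 0`` degenerates to a point mass at the target mean.
    Raises ``ValueError`` for unreachable targets (mean at 0 or 1 with
    nonzero SD, or an SD beyond what a logit-normal supports at that mean).
    """
    if not (0.0 <= target_mean <= 1.0):
        raise ValueError("target mean must be in [0, 1]")
    if target_sd < 0:
        raise ValueError("target SD must be nonnegative")
    if target_sd == 0.0:
        return float(special.logit(np.clip(target_mean, 1e-12, 1 - 1e-12))), 0.0
    if target_mean in (0.0, 1.0):
        raise ValueError("mean at the boundary admits no dispersion")
    max_sd = float(np.sqrt(target_mean * (1 - target_mean)))
    if target_sd >= 0.98 * max_sd:
        raise ValueError(
            f"SD {target_sd} unreachable for mean {target_mean} "
            f"(Bernoulli bound {max_sd:.3f})"
        )

    def resid(x):
        m, s = _logit_normal_moments(x[0], np.exp(x[1]))
        return [m - target_mean, s - target_sd]

    x0 = [float(special.logit(target_mean)), 0.0]
    sol = optimize.root(resid, x0, method="hybr", tol=1e-12)
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-8:
        raise ValueError(
            f"calibration failed for mean={target_mean}, sd={target_sd}"
        )
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def sample_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw latent participants for every condition cell.

    Returns a participant table with columns ``participant_id``,
    ``instrumentality``, ``personal_force``, ``sex``, ``D_true``,
    ``U_true``, ``total_time``.  Reproducible from ``spec.seed``.
    """
    if not spec.cells:
        raise ValueError("spec has no condition cells")
    if not (-1.0 < spec.rho_du < 1.0):
        raise ValueError("rho_du must be in (-1, 1)")
    rng = np.random.default_rng(spec.seed)
    sexes = sorted(spec.sex_probs)
    sex_p = np.array([spec.sex_probs[s] for s in sexes], dtype=float)
    sex_p = sex_p / sex_p.sum()

    frames = []
    pid = 0
    for cond in sorted(spec.cells):
        d_mean, d_sd, u_mean, u_sd = spec.cells[cond]
        n = int(spec.n_per_cell[cond])
        if n < 1:
            raise ValueError(f"cell {cond} has n < 1")
        mu_d, s_d = calibrate_logit_normal(d_mean, d_sd)
        mu_u, s_u = calibrate_logit_normal(u_mean, u_sd)

        z = rng.standard_normal((n, 2))
        z_u = spec.rho_du * z[:, 0] + np.sqrt(1 - spec.rho_du**2) * z[:, 1]
        d_true = special.expit(mu_d + s_d * z[:, 0]) if s_d > 0 else np.full(n, d_mean)
        u_true = special.expit(mu_u + s_u * z_u) if s_u > 0 else np.full(n, u_mean)

        frames.append(
            pd.DataFrame(
                {
                    "participant_id": [f"p{pid + i:05d}" for i in range(n)],
                    "instrumentality": cond[0],
                    "personal_force": cond[1],
                    "sex": rng.choice(sexes, size=n, p=sex_p),
                    "D_true": d_true,
                    "U_true": u_true,
                    "total_time": np.exp(
                        spec.time_log_mean
                        + spec.time_log_sd * rng.standard_normal(n)
                    ),
                }
            )
        )
        pid += n
    return pd.concat(frames, ignore_index=True)


def simulate_trials(
    cohort: pd.DataFrame,
    seed: int,
    orders: dict | None = None,
    n_orders_per_condition: int = 5,
) -> pd.DataFrame:
    """Bernoulli trial responses from the processing tree.

    Each participant responds to the 20-item battery of their condition in
    one of the condition's frozen semi-random presentation orders (five per
    condition by default, mirroring the study design; participants cycle
    through them).  ``orders`` may pre-supply ``{condition: [PresentationOrder,
    ...]}`` to skip order generation.

    Returns the trial table with columns ``participant_id``, ``item_id``,
    ``congruency``, ``instrumentality``, ``personal_force``, ``position``,
    ``response`` (``reject_harm``/``accept_harm``).
    """
    rng = np.random.default_rng(seed)
    conds = sorted(
        set(zip(cohort["instrumentality"], cohort["personal_force"]))
    )
    batteries = {c: standard_battery(*c) for c in conds}
    if orders is None:
        orders = {
            c: freeze_orders(
                batteries[c], seed=int(rng.integers(2**31)), n_orders=n_orders_per_condition
            )
            for c in conds
        }
    cong_of = {
        c: {it.item_id: it.congruency for it in batteries[c]} for c in conds
    }
    # pre-resolve each order into id/congruency arrays
    order_ids = {
        c: [np.array(o.item_ids) for o in orders[c]] for c in conds
    }
    order_cong = {
        c: [
            np.array([cong_of[c][i] for i in o.item_ids]) for o in orders[c]
        ]
        for c in conds
    }

    cols: dict[str, list] = {k: [] for k in (
        "participant_id", "item_id", "congruency", "instrumentality",
        "personal_force", "position", "response",
    )}
    counters = {c: 0 for c in conds}
    positions = np.arange(20)
    for rec in cohort.to_dict("records"):
        cond = (rec["instrumentality"], rec["personal_force"])
        k = counters[cond] % len(order_ids[cond])
        counters[cond] += 1
        ids = order_ids[cond][k]
        congs = order_cong[cond][k]
        p_cong, p_incong = tree_probabilities(rec["D_true"], rec["U_true"])
        p = np.where(congs == "congruent", p_cong, p_incong)
        reject = rng.random(len(ids)) < p
        cols["participant_id"].append(np.repeat(rec["participant_id"], len(ids)))
        cols["item_id"].append(ids)
        cols["congruency"].append(congs)
        cols["instrumentality"].append(np.repeat(cond[0], len(ids)))
        cols["personal_force"].append(np.repeat(cond[1], len(ids)))
        cols["position"].append(positions)
        cols["response"].append(np.where(reject, "reject_harm", "accept_harm"))
    return pd.DataFrame({k: np.concatenate(v) for k, v in cols.items()})


def inject_artifacts(
    participants: pd.DataFrame,
    trials: pd.DataFrame,
    spec: CohortSpec,
    outlier_log_offset: float = 12.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Add QC challenges: exact duplicate entries and extreme-time outliers.

    The number injected is ``round(rate * n)`` for each artifact type.
    Duplicates replicate a participant's row and all their trial rows
    verbatim (the same person submitting twice).  Outliers get their total
    time multiplied by exp(+/- ``outlier_log_offset`` * time_log_sd),
    alternating slow/fast, far enough out to clear a 3-SD rule even after
    the injected extremes inflate the sample SD.  Ground truth lives in the
    boolean columns ``injected_duplicate`` and ``injected_outlier``.
    """
    for rate in (spec.duplicate_rate, spec.outlier_rate):
        if not (0.0 <= rate <= 1.0):
            raise ValueError("artifact rates must lie in [0, 1]")
    rng = np.random.default_rng(spec.seed + 1)
    parts = participants.copy()
    parts["injected_duplicate"] = False
    parts["injected_outlier"] = False
    n = len(parts)

    n_out = int(round(spec.outlier_rate * n))
    if n_out:
        idx = rng.choice(n, size=n_out, replace=False)
        sign = np.where(np.arange(n_out) % 2 == 0, -1.0, 1.0)  # first one fast
        factor = np.exp(sign * outlier_log_offset * spec.time_log_sd)
        parts.loc[parts.index[idx], "total_time"] = (
            parts.loc[parts.index[idx], "total_time"].to_numpy() * factor
        )
        parts.loc[parts.index[idx], "injected_outlier"] = True

    n_dup = int(round(spec.duplicate_rate * n))
    trials_out = trials
    if n_dup:
        idx = rng.choice(n, size=n_dup, replace=False)
        dup_rows = parts.iloc[idx].copy()
        dup_rows["injected_duplicate"] = True
        parts.loc[parts.index[idx], "injected_duplicate"] = True
        parts = pd.concat([parts, dup_rows], ignore_index=True)
        dup_ids = dup_rows["participant_id"].tolist()
        dup_trials = trials[trials["participant_id"].isin(dup_ids)]
        trials_out = pd.concat([trials, dup_trials], ignore_index=True)

    return parts, trials_out
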