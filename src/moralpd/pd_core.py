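"""Closed-form process-dissociation parameter estimation.

The processing-tree model for one trial: with probability U the
outcome-maximization (utilitarian) inclination drives the response; with
probability 1 - U it does not, in which case the harm-rejection
(deontological) inclination drives the response with probability D.  For
congruent dilemmas both routes reject the harmful action, so

    p(harm unacceptable | congruent)   = U + (1 - U) * D
    p(harm unacceptable | incongruent) = (1 - U) * D

Solving the two equations for the parameters gives the per-participant
estimates

    U = p(unacc | congruent) - p(unacc | incongruent)
    D = p(unacc | incongruent) / (1 - U)

With errorful finite-trial proportions U can come out negative (or D above
one); for the regression analyses negative estimates are set to 0, the
estimates are capped at 1, and values are rounded to the 1/weight grid
(weight 20, one unit per dilemma) so they can enter a weighted binomial
logit as integer success counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import preprocessing

#: Number of dilemmas behind each PD parameter (regression weight).
PD_WEIGHT = 20
#: Number of incongruent dilemmas behind the conventional measure.
CONVENTIONAL_WEIGHT = 10


def tree_probabilities(d, u):
    """Forward model: response probabilities implied by (D, U).

    Returns ``(p_unacc_congruent, p_unacc_incongruent)``; accepts scalars or
    arrays.
    """
    d = np.asarray(d, dtype=float)
    u = np.asarray(u, dtype=float)
    p_incong = (1.0 - u) * d
    p_cong = u + p_incong
    return p_cong, p_incong


def estimate_pd(agg: pd.DataFrame) -> pd.DataFrame:
    """Per-participant PD estimates from congruent/incongruent proportions.

    ``agg`` needs columns ``participant_id``, ``p_unacc_cong`` and
    ``p_unacc_incong`` (e.g. from :func:`moralpd.preprocessing.aggregate`).

    Returns one row per participant with the raw algebraic solutions
    (``U_raw``, ``D_raw``), the conditioned values used downstream (``U``,
    ``D``, clamped into [0, 1], with the conditioned D computed from the
    clamped U), grid values on the 1/20 grid (``grid_U``, ``grid_D``), and
    flags.  When U = 1 the incongruent equation carries no information about
    D; ``D`` is left undefined (NaN) and ``d_undefined`` is set, so such
    participants can be excluded from D analyses explicitly rather than
    silently zeroed.
    """
    p_cong = np.asarray(agg["p_unacc_cong"], dtype=float)
    p_incong = np.asarray(agg["p_unacc_incong"], dtype=float)
    if ((p_cong < 0) | (p_cong > 1) | (p_incong < 0) | (p_incong > 1)).any():
        raise ValueError("proportions must lie in [0, 1]")

    u_raw = p_cong - p_incong
    u = np.clip(u_raw, 0.0, 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        d_raw = np.where(u_raw < 1.0, p_incong / (1.0 - u_raw), np.nan)
        d = np.where(u < 1.0, np.clip(p_incong / (1.0 - u), 0.0, 1.0), np.nan)

    out = pd.DataFrame(
        {
            "participant_id": agg["participant_id"].to_numpy(),
            "U_raw": u_raw,
            "D_raw": d_raw,
            "U": u,
            "D": d,
            "u_clamped": u_raw < 0,
            "d_clamped": (d_raw > 1.0) | (d_raw < 0.0),
            "d_undefined": ~(u < 1.0),
        }
    )
    out["grid_U"] = condition_for_regression(out["U"].to_numpy(), PD_WEIGHT)
    out["grid_D"] = condition_for_regression(out["D"].to_numpy(), PD_WEIGHT)
    return out


def condition_for_regression(values, weight: int = PD_WEIGHT):
    """Round clamped parameter values to the nearest multiple of 1/weight.

    Clamping must already have been applied (values in [0, 1] or NaN).
    Exact half-grid ties round up (away from zero); the two documented
    roundings 0.42 -> 0.40 and 0.44 -> 0.45 are plain nearest-multiple.
    A small epsilon absorbs binary-representation slop so that e.g. 0.425
    (stored as 8.499999...e0 when scaled by 20) still ties upward.
    """
    if int(weight) < 1:
        raise ValueError("weight must be a positive integer")
    v = np.asarray(values, dtype=float)
    if np.nanmin(v, initial=0.0) < 0 or np.nanmax(v, initial=0.0) > 1:
        raise ValueError("values must be clamped into [0, 1] before rounding")
    scaled = v * weight
    rounded = np.floor(scaled + 0.5 + 1e-9) / weight
    rounded = np.clip(rounded, 0.0, 1.0)
    if np.isscalar(values):
        return float(rounded)
    return rounded


def conventional_measure(trials: pd.DataFrame) -> pd.DataFrame:
    """Proportion of harm-accepting responses among the 10 incongruent items.

    High scores indicate predominance of the outcome-maximization tendency,
    low scores predominance of harm rejection; this is the one-dimensional
    summary that the PD parameters decompose.  Participants missing
    incongruent trials are flagged, not dropped.
    """
    inc = trials[trials["congruency"] == "incongruent"]
    grouped = inc.groupby("participant_id", sort=True)
    out = grouped.agg(
        n_incong=("response", "size"),
        conventional=("response", lambda r: float(np.mean(r == "accept_harm"))),
    ).reset_index()
    out["incomplete"] = out["n_incong"] != CONVENTIONAL_WEIGHT
    out["weight"] = CONVENTIONAL_WEIGHT
    return out


def group_level_estimate(agg: pd.DataFrame) -> dict:
    """PD parameters from *pooled* proportions (not used by the per-person
    analyses; provided for descriptive comparison only)."""
    p_cong = float(np.mean(agg["p_unacc_cong"]))
    p_incong = float(np.mean(agg["p_unacc_incong"]))
    u = p_cong - p_incong
    d = p_incong / (1.0 - u) if u < 1 else float("nan")
    return {"p_unacc_cong": p_cong, "p_unacc_incong": p_incong, "U": u, "D": d}


def cell_summaries(
    estimates: pd.DataFrame,
    participants: pd.DataFrame,
    conventional: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-condition means/SDs of D, U and the conventional measure, plus the
    within-cell Pearson correlation between D and U.

    ``participants`` supplies the condition factors (``instrumentality``,
    ``personal_force``) per ``participant_id``.  Cells need at least two
    participants; participants with undefined D reduce the effective n
    reported for D and the correlation.
    """
    from .correlations import pearson  # local import to avoid a cycle

    cols = ["participant_id", "instrumentality", "personal_force"]
    merged = estimates.merge(participants[cols], on="participant_id", how="left")
    if conventional is not None:
        merged = merged.merge(
            conventional[["participant_id", "conventional"]],
            on="participant_id",
            how="left",
        )
    else:
        merged["conventional"] = np.nan

    rows = []
    for (instr, pf), cell in merged.groupby(
        ["instrumentality", "personal_force"], sort=True
    ):
        if len(cell) < 2:
            raise ValueError(
                f"cell ({instr}, {pf}) has fewer than 2 participants"
            )
        d_ok = cell["D"].notna()
        both = cell[d_ok]
        if len(both) >= 4 and both["D"].std() > 0 and both["U"].std() > 0:
            corr = pearson(both["D"].to_numpy(), both["U"].to_numpy())
            r, r_p = corr.r, corr.p
        else:
            r, r_p = float("nan"), float("nan")
        rows.append(
            {
                "instrumentality": instr,
                "personal_force": pf,
                "n": int(len(cell)),
                "n_d_defined": int(d_ok.sum()),
                "d_mean": float(cell["D"].mean()),
                "d_sd": float(cell["D"].std()),
                "u_mean": float(cell["U"].mean()),
                "u_sd": float(cell["U"].std()),
                "conventional_mean": float(cell["conventional"].mean()),
                "conventional_sd": float(cell["conventional"].std()),
                "du_correlation": r,
                "du_correlation_p": r_p,
            }
        )
    return pd.DataFrame(rows)


def estimate_from_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Convenience: aggregate trials and estimate PD parameters in one step."""
    agg = preprocessing.aggregate(trials)
    return estimate_pd(agg)
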