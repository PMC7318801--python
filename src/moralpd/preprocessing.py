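"""Exclusion rules and trial aggregation.

The exclusion pipeline runs in a fixed order: exact-duplicate removal first,
then total-processing-time outliers (|z| > 3 on the log scale, computed in a
single pass on the post-duplicate-removal sample), then an optional
minimum-total-time compliance rule.  Each step logs what it removed and why.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

_ARTIFACT_COLS = ("injected_duplicate", "injected_outlier")


def remove_duplicates(
    participants: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop repeated participant entries, keeping the first occurrence.

    A duplicate is a row whose participant id and full payload (excluding
    any simulation ground-truth label columns) already occurred.  Returns
    ``(deduplicated table, removal log)``.
    """
    payload_cols = [c for c in participants.columns if c not in _ARTIFACT_COLS]
    dup_mask = participants.duplicated(subset=payload_cols, keep="first")
    log = pd.DataFrame(
        {
            "participant_id": participants.loc[dup_mask, "participant_id"],
            "rule": "duplicate",
            "statistic": np.nan,
            "threshold": np.nan,
        }
    ).reset_index(drop=True)
    return participants[~dup_mask].reset_index(drop=True), log


def flag_time_outliers(
    participants: pd.DataFrame, k_sd: float = 3.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag participants whose log total time is > ``k_sd`` SDs from the mean.

    The mean and (sample) SD of the logarithmized total processing time are
    computed once on the input table, not iteratively re-estimated after
    removals.  Zero variance yields no outliers and a warning.  Returns the
    table with boolean column ``time_outlier`` plus a log of flagged rows.
    """
    t = participants["total_time"].to_numpy(dtype=float)
    if (t <= 0).any():
        raise ValueError("total_time must be positive")
    log_t = np.log(t)
    mean, sd = float(np.mean(log_t)), float(np.std(log_t, ddof=1))
    out = participants.copy()
    if sd <= 1e-12 * max(1.0, abs(mean)) or not np.isfinite(sd):
        warnings.warn("zero variance in log processing time; no outliers flagged")
        out["time_outlier"] = False
        z = np.zeros(len(out))
    else:
        z = (log_t - mean) / sd
        out["time_outlier"] = np.abs(z) > k_sd
    log = pd.DataFrame(
        {
            "participant_id": out.loc[out["time_outlier"], "participant_id"],
            "rule": "log_time_outlier",
            "statistic": z[out["time_outlier"].to_numpy()],
            "threshold": k_sd,
        }
    ).reset_index(drop=True)
    return out, log


def apply_exclusions(
    participants: pd.DataFrame,
    trials: pd.DataFrame,
    k_sd: float = 3.0,
    min_total_time: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full exclusion pipeline: duplicates, time outliers, optional compliance.

    ``min_total_time`` (seconds) implements the instruction-compliance rule
    for implausibly fast sessions; it is disabled by default because no
    published threshold exists.  Returns ``(retained participants, retained
    trials, exclusion log)``.  Rerunning on its own output is a no-op.
    """
    parts, dup_log = remove_duplicates(participants)
    trials = trials.drop_duplicates(
        subset=["participant_id", "item_id"], keep="first"
    ).reset_index(drop=True)

    parts, out_log = flag_time_outliers(parts, k_sd=k_sd)
    logs = [dup_log, out_log]
    keep = ~parts["time_outlier"]

    if min_total_time is not None:
        fast = parts["total_time"] < float(min_total_time)
        logs.append(
            pd.DataFrame(
                {
                    "participant_id": parts.loc[fast & keep, "participant_id"],
                    "rule": "min_total_time",
                    "statistic": parts.loc[fast & keep, "total_time"],
                    "threshold": float(min_total_time),
                }
            )
        )
        keep &= ~fast

    retained = parts[keep].drop(columns=["time_outlier"]).reset_index(drop=True)
    log = pd.concat(logs, ignore_index=True)
    trials = trials[
        trials["participant_id"].isin(set(retained["participant_id"]))
    ].reset_index(drop=True)
    return retained, trials, log


def aggregate(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-participant proportions of harm-unacceptable responses.

    Counts ``reject_harm`` responses within each congruency.  Participants
    with missing trials (fewer than 10 per congruency) are flagged via
    ``incomplete`` rather than dropped; the result is invariant to trial
    order.
    """
    reject = (trials["response"] == "reject_harm").astype(float)
    df = trials.assign(_reject=reject)
    wide = (
        df.groupby(["participant_id", "congruency"], sort=True)["_reject"]
        .agg(["size", "mean"])
        .unstack("congruency")
    )
    out = pd.DataFrame(
        {
            "participant_id": wide.index,
            "n_cong": wide.get(("size", "congruent"), pd.Series(0, wide.index))
            .fillna(0)
            .astype(int),
            "n_incong": wide.get(("size", "incongruent"), pd.Series(0, wide.index))
            .fillna(0)
            .astype(int),
            "p_unacc_cong": wide.get(("mean", "congruent")),
            "p_unacc_incong": wide.get(("mean", "incongruent")),
        }
    ).reset_index(drop=True)
    out["incomplete"] = (out["n_cong"] != 10) | (out["n_incong"] != 10)
    return out


def acceptance_rates(agg: pd.DataFrame) -> dict:
    """Grand-mean harm-acceptance rates by congruency (descriptive contrast)."""
    acc_cong = 1.0 - agg["p_unacc_cong"]
    acc_incong = 1.0 - agg["p_unacc_incong"]
    return {
        "accept_congruent_mean": float(acc_cong.mean()),
        "accept_congruent_sd": float(acc_cong.std()),
        "accept_incongruent_mean": float(acc_incong.mean()),
        "accept_incongruent_sd": float(acc_incong.std()),
    }
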