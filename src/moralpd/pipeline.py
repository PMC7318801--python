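"""End-to-end orchestration: simulate -> preprocess -> estimate -> analyze.

A run is fully determined by an :class:`AnalysisConfig` (serializable to
YAML) and its seed: the same config yields byte-identical report JSON.  The
stage order mirrors the analysis of the modeled experiments: exclusions,
congruency acceptance contrast, PD parameter estimation, the weighted logit
mixed model with likelihood-ratio tests, quasibinomial follow-up GLMs,
conventional-measure analysis, sex-covariate analysis, condition-cell
correlations with pairwise Fisher comparisons, and the sensitivity power
analysis.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import correlations, glm, pd_core, preprocessing, reference
from .cohort import CohortSpec, inject_artifacts, sample_cohort, simulate_trials
from .power import SensitivitySpec, sensitivity_effect

__version__ = "0.1.0"


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything a pipeline run depends on, besides the package version."""

    experiment: int = 3
    n_per_cell: int | None = None
    seed: int = 0
    rho_du: float = 0.0
    duplicate_rate: float = 0.0
    outlier_rate: float = 0.0
    k_sd: float = 3.0
    min_total_time: float | None = None
    weight: int = 20
    overdispersion_threshold: float = 1.5
    correlation_tail: str = correlations.TWO_SIDED
    power_rho: float | None = None  # None: use the observed overall D-U r
    power_alpha: float = 0.05
    power_target: float = 0.80

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _terms_for_experiment(experiment: int) -> list[str]:
    if experiment == 1:
        return ["parameter", "instrumentality", "parameter:instrumentality"]
    return [
        "parameter",
        "instrumentality",
        "personal_force",
        "parameter:instrumentality",
        "parameter:personal_force",
        "instrumentality:personal_force",
        "parameter:instrumentality:personal_force",
    ]


def _between_terms(experiment: int) -> list[str]:
    if experiment == 1:
        return ["instrumentality"]
    return ["instrumentality", "personal_force", "instrumentality:personal_force"]


def _fit_table(fit: glm.FitResult) -> list[dict]:
    return fit.table.round(10).to_dict("records")


def _lrt_dict(res: glm.LRTResult) -> dict:
    return {"chi2": res.chi2, "df": res.df, "p": res.p}


def _mixed_with_lrts(long, terms, weight, drop_terms):
    """Fit the mixed logit and LRT each term in ``drop_terms`` by refitting
    without it (and, for main effects, without interactions containing it)."""
    spec = glm.ModelSpec(terms=tuple(terms), weight=weight)
    full = glm.fit_mixed_logit(long, spec)
    tests = {}
    for term in drop_terms:
        reduced_terms = [t for t in terms if t != term]
        red = glm.fit_mixed_logit(
            long, glm.ModelSpec(terms=tuple(reduced_terms), weight=weight)
        )
        tests[term] = glm.lrt(full, red)
    return full, tests


def congruency_contrast(agg: pd.DataFrame, weight: int = 10) -> dict:
    """Acceptance-rate contrast between congruent and incongruent dilemmas.

    A repeated-measures logit mixed model (random intercept per participant)
    on the per-congruency acceptance counts, evaluated by LRT, with the
    descriptive acceptance rates alongside.
    """
    rows = []
    for rec in agg.to_dict("records"):
        for cong, p_unacc in (
            ("congruent", rec["p_unacc_cong"]),
            ("incongruent", rec["p_unacc_incong"]),
        ):
            rows.append(
                {
                    "participant_id": rec["participant_id"],
                    "congruency": cong,
                    "successes": int(round(weight * (1.0 - p_unacc))),
                    "trials": weight,
                }
            )
    long = pd.DataFrame(rows)
    full = glm.fit_mixed_logit(
        long, glm.ModelSpec(terms=("congruency",), weight=weight),
        random_slope=None,
    )
    null = glm.fit_mixed_logit(
        long, glm.ModelSpec(terms=(), weight=weight), random_slope=None
    )
    test = glm.lrt(full, null)
    coef = full.table[full.table["term"] == "congruency[incongruent]"].iloc[0]
    rates = preprocessing.acceptance_rates(agg)
    return {
        **rates,
        "lrt": _lrt_dict(test),
        "odds_ratio": float(coef["odds_ratio"]),
        "b": float(coef["b"]),
        "model": _fit_table(full),
    }


def run_pipeline(config: AnalysisConfig, outdir: str | Path | None = None) -> dict:
    """Execute all stages; return (and optionally write) the report bundle."""
    stage = "simulate"
    try:
        cohort_spec = CohortSpec.from_experiment(
            config.experiment,
            n_per_cell=config.n_per_cell,
            seed=config.seed,
            rho_du=config.rho_du,
            duplicate_rate=config.duplicate_rate,
            outlier_rate=config.outlier_rate,
        )
        participants = sample_cohort(cohort_spec)
        trials = simulate_trials(participants, seed=config.seed + 1)
        participants, trials = inject_artifacts(participants, trials, cohort_spec)

        stage = "preprocess"
        retained, trials_clean, excl_log = preprocessing.apply_exclusions(
            participants, trials,
            k_sd=config.k_sd, min_total_time=config.min_total_time,
        )
        agg = preprocessing.aggregate(trials_clean)

        stage = "estimate"
        estimates = pd_core.estimate_pd(agg)
        conventional = pd_core.conventional_measure(trials_clean)
        cells = pd_core.cell_summaries(estimates, retained, conventional)

        stage = "analyze"
        contrast = congruency_contrast(agg)

        long = glm.pd_long_table(estimates, retained, weight=config.weight)
        terms = _terms_for_experiment(config.experiment)
        drop = ["parameter:instrumentality"]
        if config.experiment != 1:
            drop.append("parameter:personal_force")
        mixed, mixed_lrts = _mixed_with_lrts(long, terms, config.weight, drop)

        sex_terms = terms + ["sex", "parameter:sex"]
        sex_fit, sex_lrts = _mixed_with_lrts(
            long, sex_terms, config.weight, ["sex", "parameter:sex"]
        )

        between = _between_terms(config.experiment)
        per_parameter = {}
        for param in ("D", "U"):
            sub = long[long["parameter"] == param]
            flag, dispersion = glm.overdispersion_check(
                sub, glm.ModelSpec(terms=tuple(between), weight=config.weight),
                threshold=config.overdispersion_threshold,
            )
            family = "quasibinomial" if flag else "binomial"
            spec = glm.ModelSpec(
                terms=tuple(between), weight=config.weight, family=family
            )
            fit = glm.fit_glm(sub, spec)
            tests = {}
            for term in between:
                red = glm.fit_glm(
                    sub,
                    glm.ModelSpec(
                        terms=tuple(t for t in between if t != term),
                        weight=config.weight, family=family,
                    ),
                )
                tests[term] = _lrt_dict(glm.drop_term_test(fit, red))
            per_parameter[param] = {
                "family": family,
                "dispersion": dispersion,
                "overdispersed": flag,
                "coefficients": _fit_table(fit),
                "term_tests": tests,
            }

        conv_long = conventional.rename(columns={"conventional": "p"}).merge(
            retained[["participant_id", "instrumentality", "personal_force"]],
            on="participant_id",
        )
        conv_long["successes"] = (
            conv_long["p"] * pd_core.CONVENTIONAL_WEIGHT
        ).round().astype(int)
        conv_long["trials"] = pd_core.CONVENTIONAL_WEIGHT
        conv_spec = glm.ModelSpec(
            terms=tuple(between), weight=pd_core.CONVENTIONAL_WEIGHT
        )
        conv_fit = glm.fit_glm(conv_long, conv_spec)
        conv_tests = {}
        for term in between:
            red = glm.fit_glm(
                conv_long,
                glm.ModelSpec(
                    terms=tuple(t for t in between if t != term),
                    weight=pd_core.CONVENTIONAL_WEIGHT,
                ),
            )
            conv_tests[term] = _lrt_dict(glm.drop_term_test(conv_fit, red))

        both = estimates[estimates["D"].notna()]
        overall = correlations.pearson(both["D"].to_numpy(), both["U"].to_numpy())
        cell_r = {}
        cell_n = {}
        for rec in cells.to_dict("records"):
            label = f"{rec['instrumentality']}/{rec['personal_force']}"
            if not np.isnan(rec["du_correlation"]):
                cell_r[label] = rec["du_correlation"]
                cell_n[label] = rec["n_d_defined"]
        if len(cell_r) >= 2:
            pair_rows, max_z, min_p = correlations.pairwise_condition_comparisons(
                cell_r, cell_n, tail=config.correlation_tail
            )
        else:
            pair_rows, max_z, min_p = [], float("nan"), float("nan")

        stage = "power"
        rho = config.power_rho if config.power_rho is not None else overall.r
        sens = sensitivity_effect(
            SensitivitySpec(
                n_total=int(len(retained)),
                n_groups=2,
                n_measures=2,
                rho=float(rho),
                alpha=config.power_alpha,
                power=config.power_target,
            )
        )

        stage = "report"
        bundle = {
            "meta": {
                "package_version": __version__,
                "config": config.to_dict(),
                "config_hash": config.config_hash(),
                "seed": config.seed,
            },
            "counts": {
                "n_simulated": int(len(participants)),
                "n_retained": int(len(retained)),
                "n_excluded": int(len(participants) - len(retained)),
            },
            "exclusions": excl_log.to_dict("records"),
            "congruency_contrast": contrast,
            "cell_summaries": cells.round(10).to_dict("records"),
            "mixed_model": {
                "coefficients": _fit_table(mixed),
                "loglik": mixed.loglik,
                "re_sd": list(mixed.re_sd),
                "re_corr": mixed.re_corr,
                "converged": mixed.converged,
                "singular": mixed.singular,
                "lrt": {k: _lrt_dict(v) for k, v in mixed_lrts.items()},
            },
            "sex_model": {
                "coefficients": _fit_table(sex_fit),
                "lrt": {k: _lrt_dict(v) for k, v in sex_lrts.items()},
            },
            "per_parameter_glm": per_parameter,
            "conventional_model": {
                "coefficients": _fit_table(conv_fit),
                "term_tests": conv_tests,
            },
            "correlations": {
                "overall": {
                    "r": overall.r, "n": overall.n, "t": overall.t, "p": overall.p,
                },
                "cells": [
                    {"cell": label, "r": cell_r[label], "n": cell_n[label]}
                    for label in sorted(cell_r)
                ],
                "pairwise": pair_rows,
                "max_abs_z": max_z,
                "min_p": min_p,
                "tail": config.correlation_tail,
            },
            "power_sensitivity": {
                "n_total": int(len(retained)),
                "rho": float(rho),
                "alpha": config.power_alpha,
                "target_power": config.power_target,
                "partial_eta2": sens.partial_eta2,
                "f2": sens.f2,
                "noncentrality": sens.noncentrality,
                "critical_f": sens.critical_f,
                "df1": sens.df1,
                "df2": sens.df2,
            },
        }
    except Exception as err:  # surface the failing stage, per contract
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        participants.to_csv(outdir / "participants.csv", index=False)
        trials.to_csv(outdir / "trials.csv", index=False)
        excl_log.to_csv(outdir / "exclusions.csv", index=False)
        estimates.to_csv(outdir / "estimates.csv", index=False)
        cells.to_csv(outdir / "cell_summaries.csv", index=False)
        mixed.table.to_csv(outdir / "mixed_model.csv", index=False)
        for param in ("D", "U"):
            pd.DataFrame(per_parameter[param]["coefficients"]).to_csv(
                outdir / f"glm_{param}.csv", index=False
            )
        conv_fit.table.to_csv(outdir / "conventional_model.csv", index=False)
        pd.DataFrame(pair_rows).to_csv(
            outdir / "correlation_comparisons.csv", index=False
        )
        (outdir / "report.json").write_text(
            json.dumps(bundle, sort_keys=True, indent=1, allow_nan=True)
        )
    return bundle


def make_fixture(name: str) -> dict:
    """Small seeded datasets for tests and demos.

    ``tiny-exp1``: 8 participants (4 per instrumentality condition) with a
    valid 20-item battery each, simulated without artifacts.
    """
    if name == "tiny-exp1":
        spec = CohortSpec.from_experiment(1, n_per_cell=4, seed=20)
        participants = sample_cohort(spec)
        trials = simulate_trials(participants, seed=21)
        return {"participants": participants, "trials": trials, "spec": spec}
    raise KeyError(f"unknown fixture {name!r}")
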