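"""Replicated simulation studies: model recovery and the eta / M-ratio map.

Each study repeats the loop draw parameters -> calibrate boundaries ->
simulate an experiment -> fit -> score, and returns one row per
replicate plus summary statistics.  Replicate failures (non-convergence,
out-of-range efficiency) are logged and excluded, with counts reported.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .efficiency import cncb_efficiency
from .exceptions import CNCBError
from .fit import fit_cncb, lr_test
from .metad import fit_metad
from .model import ConfidenceParams, SensoryParams
from .simulate import (
    SimulationDesign,
    calibrate_boundaries,
    simulate_dataset,
    study_parameter_ranges,
    triangular_proportions,
)

__all__ = ["run_study", "model_recovery_rates", "loglog_slope"]

log = logging.getLogger("cncb")


def _observer_from_draw(ranges, params) -> tuple[SensoryParams, ConfidenceParams]:
    sens = SensoryParams(mu=ranges.strengths, sigma_s=params["sigma_s"],
                         theta_s=params["theta_s"])
    props = triangular_proportions(ranges.n_levels, params["delta"])
    b = calibrate_boundaries(sens, params["sigma_c"], params["alpha"], props)
    return sens, ConfidenceParams(params["sigma_c"], params["alpha"], b)


def _recovery_rep(ranges, params, rng, fit_options, alpha_level):
    sens, conf = _observer_from_draw(ranges, params)
    design = SimulationDesign(n_trials=ranges.n_trials, n_levels=ranges.n_levels)
    _, counts = simulate_dataset(sens, conf, design, rng=rng)
    fit0 = fit_cncb(counts, "no_boost", options=fit_options)
    fit1 = fit_cncb(counts, "with_boost", options=fit_options)
    lam, p = lr_test(fit0, fit1)
    return {
        **{f"true_{k}": v for k, v in params.items()},
        "logL_no_boost": fit0.logL,
        "logL_with_boost": fit1.logL,
        "est_sigma_c": fit1.conf.sigma_c,
        "est_alpha": fit1.conf.alpha,
        "lambda_lr": lam,
        "p_value": p,
        "chosen_model": 2 if p < alpha_level else 1,
    }


def _mratio_rep(ranges, params, rng, fit_options):
    sens, conf = _observer_from_draw(ranges, params)
    design = SimulationDesign(n_trials=ranges.n_trials, n_levels=ranges.n_levels)
    _, counts = simulate_dataset(sens, conf, design, rng=rng)
    fit = fit_cncb(counts, "with_boost", options=fit_options)
    eff = cncb_efficiency(fit)
    md = fit_metad(counts)
    return {
        **{f"true_{k}": v for k, v in params.items()},
        "est_sigma_c": fit.conf.sigma_c,
        "est_alpha": fit.conf.alpha,
        "eta": eff.eta,
        "tau_human": eff.tau_human,
        "tau_ideal": eff.tau_ideal,
        "d_prime": md.d_prime,
        "meta_d": md.meta_d,
        "m_ratio": md.m_ratio,
    }


def run_study(
    study_id: str,
    reps: int = 100,
    seed: int | None = None,
    fit_options: dict | None = None,
    alpha_level: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Run one replicated simulation study.

    ``model_recovery`` simulates half the replicates from the no-boost
    model and half from the with-boost model, fits both nested variants
    to every dataset and applies the chi-square(1) likelihood-ratio test
    at ``alpha_level``.  ``mratio_grid`` draws observers on the declared
    ranges and records CNCB efficiency alongside the M-ratio.

    Returns (per-replicate table, summary dict).  Identical (study_id,
    reps, seed) give identical tables.
    """
    ranges = study_parameter_ranges(study_id)
    rng = np.random.default_rng(seed)
    rows = []
    failures = 0
    if study_id == "model_recovery":
        for rep in range(reps):
            true_model = 1 if rep % 2 == 0 else 2
            params = ranges.draw(rng, alpha=0.0 if true_model == 1 else None)
            try:
                row = _recovery_rep(ranges, params, rng, fit_options, alpha_level)
            except CNCBError as exc:  # pragma: no cover - rare numeric edge
                log.warning("replicate %d failed: %s", rep, exc)
                failures += 1
                continue
            row.update({"rep": rep, "true_model": true_model})
            rows.append(row)
        table = pd.DataFrame(rows)
        summary = model_recovery_rates(table)
    elif study_id == "mratio_grid":
        for rep in range(reps):
            params = ranges.draw(rng)
            try:
                row = _mratio_rep(ranges, params, rng, fit_options)
            except CNCBError as exc:
                log.warning("replicate %d failed: %s", rep, exc)
                failures += 1
                continue
            row["rep"] = rep
            rows.append(row)
        table = pd.DataFrame(rows)
        summary = {
            "slope_loglog": loglog_slope(table["m_ratio"], table["eta"]),
            "median_eta": float(table["eta"].median()),
            "median_m_ratio": float(table["m_ratio"].median()),
        }
    else:
        raise ValueError(f"no study loop defined for {study_id!r}")
    summary["failures"] = failures
    summary["reps"] = reps
    summary["seed"] = seed
    return table, summary


def model_recovery_rates(table: pd.DataFrame) -> dict:
    """Recovery rates and the model-discrimination sensitivity.

    Treating 'chose model 1 when model 1 generated' as a hit and 'chose
    model 1 when model 2 generated' as a false alarm, the discrimination
    d' is z(hit) - z(fa) and the criterion c = -(z(hit) + z(fa)) / 2.
    """
    m1 = table[table["true_model"] == 1]
    m2 = table[table["true_model"] == 2]
    r1 = float((m1["chosen_model"] == 1).mean()) if len(m1) else np.nan
    r2 = float((m2["chosen_model"] == 2).mean()) if len(m2) else np.nan

    def _z(p, n):
        return ndtri(np.clip(p, 0.5 / max(n, 1), 1 - 0.5 / max(n, 1)))

    zh, zf = _z(r1, len(m1)), _z(1 - r2, len(m2))
    return {
        "recovery_model1": r1,
        "recovery_model2": r2,
        "d_prime_models": float(zh - zf),
        "criterion_models": float(-(zh + zf) / 2.0),
        "n_model1": int(len(m1)),
        "n_model2": int(len(m2)),
    }


def loglog_slope(m_ratio, eta) -> float:
    """OLS slope of log(eta) on log(M-ratio), on replicates where both are
    positive."""
    m = np.asarray(m_ratio, float)
    e = np.asarray(eta, float)
    keep = (m > 0) & (e > 0) & np.isfinite(m) & np.isfinite(e)
    slope, _ = np.polyfit(np.log(m[keep]), np.log(e[keep]), 1)
    return float(slope)
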