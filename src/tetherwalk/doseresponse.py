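"""Nonlinear dose-response fitting: Hill, biphasic Hill and Langmuir inhibition.

Binding titrations follow the Hill isotherm R(c) = R_max c^h / (c^h + K_D^h).
Kinesin run frequency vs MAP7 is biphasic — activation by recruitment at
low concentration, inhibition by site competition at high concentration —
and is fit by the product form

    f(c) = A * [c^h1 / (c^h1 + EC50^h1)] * [IC50^h2 / (c^h2 + IC50^h2)] + f0,

reported as half-max activation (EC50) and inhibition (IC50).  Dynein run
frequency is purely inhibitory and follows the single-site Langmuir form
f(c) = f0 * IC50 / (IC50 + c).

All fits are weighted least squares (weights 1/sd^2 when the table carries
an sd column and ``weighted=True``), run from multiple log-spaced starts
because the biphasic surface is multimodal, with standard errors from the
covariance of the linearized fit; a seeded residual bootstrap is available
as a cross-check.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "FitResult",
    "hill",
    "biphasic_hill",
    "langmuir_inhibition",
    "fit_hill",
    "fit_biphasic_hill",
    "fit_langmuir_inhibition",
    "bootstrap_se",
]


def hill(c, r_max, kd, h):
    """Hill isotherm; defined as 0 at c = 0."""
    c = np.asarray(c, dtype=float)
    ch = np.where(c > 0, c, np.nan) ** h
    return np.where(c > 0, r_max * ch / (ch + kd ** h), 0.0)


def biphasic_hill(c, amplitude, ec50, h1, ic50, h2, f0):
    """Product of an activating and an inhibiting Hill term plus baseline."""
    c = np.asarray(c, dtype=float)
    ch1 = np.where(c > 0, c, np.nan) ** h1
    act = np.where(c > 0, ch1 / (ch1 + ec50 ** h1), 0.0)
    inh = ic50 ** h2 / (np.where(c > 0, c, 0.0) ** h2 + ic50 ** h2)
    return amplitude * act * inh + f0

def langmuir_inhibition(c, f0, ic50):
    """Single-site competitive suppression f0 * IC50 / (IC50 + c)."""
    c = np.asarray(c, dtype=float)
    return f0 * ic50 / (ic50 + c)


@dataclass
class FitResult:
    """Outcome of one dose-response fit.

    ``params``/``se`` map parameter names to estimates and standard
    errors; ``flags`` collects soft diagnostics ('non_identifiable',
    'no_biphasic_evidence', ...) instead of raising, so pipelines can
    carry degenerate fits through.
    """

    model: str
    params: dict[str, float]
    se: dict[str, float]
    rss: float
    n: int
    aic: float
    converged: bool
    flags: list[str] = field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = {
            "model": self.model,
            "params": self.params,
            "se": self.se,
            "rss": self.rss,
            "n": self.n,
            "aic": self.aic,
            "converged": self.converged,
            "flags": self.flags,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _aic(rss: float, n: int, k: int) -> float:
    return n * np.log(max(rss, 1e-300) / n) + 2 * k


def _extract(table: pd.DataFrame, weighted: bool):
    c = table["concentration_nM"].to_numpy(dtype=float)
    r = table["response"].to_numpy(dtype=float)
    sigma = None
    if weighted and "sd" in table.columns:
        sd = table["sd"].to_numpy(dtype=float)
        if np.all(np.isfinite(sd)) and np.all(sd > 0):
            sigma = sd
    return c, r, sigma


def _multistart_fit(model, c, r, sigma, starts, bounds, names: list[str]):
    best = None
    for p0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(
                    model, c, r, p0=p0, sigma=sigma, absolute_sigma=False,
                    bounds=bounds, maxfev=20000,
                )
            rss = float(np.sum((model(c, *popt) - r) ** 2))
            if best is None or rss < best[2]:
                best = (popt, pcov, rss)
        except (RuntimeError, ValueError):
            continue
    return best


def fit_hill(table: pd.DataFrame, weighted: bool = True) -> FitResult:
    """Fit the Hill isotherm to a titration table; reports K_D, h and R_max.

    Needs >= 4 distinct concentrations.  A response with no dependence on
    concentration is flagged 'non_identifiable' rather than raising.
    """
    c, r, sigma = _extract(table, weighted)
    if len(np.unique(c)) < 4:
        raise ValueError("fit_hill needs at least 4 distinct concentrations")
    names = ["r_max", "kd", "h"]
    if np.ptp(r) < 1e-12 * (abs(np.mean(r)) + 1):
        return FitResult("hill", dict.fromkeys(names, np.nan), dict.fromkeys(names, np.nan),
                         float(np.sum((r - r.mean()) ** 2)), len(r), np.nan, False,
                         ["non_identifiable"])
    r_max0 = float(np.max(r))
    kd_grid = np.geomspace(max(c[c > 0].min(), 1e-3), max(c.max(), 1.0), 5)
    starts = [(r_max0, kd, 1.0) for kd in kd_grid]
    bounds = ([0.0, 1e-6, 0.2], [np.inf, 1e9, 6.0])
    best = _multistart_fit(hill, c, r, sigma, starts, bounds, names)
    if best is None:
        return FitResult("hill", dict.fromkeys(names, np.nan), dict.fromkeys(names, np.nan),
                         np.nan, len(r), np.nan, False, ["no_convergence"])
    popt, pcov, rss = best
    se = np.sqrt(np.clip(np.diag(pcov), 0, None))
    return FitResult("hill", dict(zip(names, map(float, popt))),
                     dict(zip(names, map(float, se))), rss, len(r),
                     _aic(rss, len(r), len(names)), True)


def fit_biphasic_hill(table: pd.DataFrame, weighted: bool = True) -> FitResult:
    """Fit the biphasic (activation x inhibition) Hill model.

    Needs >= 6 distinct concentrations.  The result is compared with the
    single Hill fit by AIC; when the single Hill wins, or the optimum does
    not satisfy EC50 < IC50, the result is flagged 'no_biphasic_evidence'
    / 'ec50_not_below_ic50' (the parameters are still reported).
    """
    c, r, sigma = _extract(table, weighted)
    if len(np.unique(c)) < 6:
        raise ValueError("fit_biphasic_hill needs at least 6 distinct concentrations")
    names = ["amplitude", "ec50", "h1", "ic50", "h2", "f0"]
    cpos = c[c > 0]
    lo, hi = cpos.min(), c.max()
    amp0 = float(np.max(r) - np.min(r)) or 1.0
    grid = np.geomspace(lo, hi, 5)
    starts = [
        (amp0 * 2, ec, 1.0, ic, 1.0, float(np.min(r)))
        for ec in grid for ic in grid if ec < ic
    ] or [(amp0 * 2, lo, 1.0, hi, 1.0, float(np.min(r)))]
    bounds = ([0.0, 1e-6, 0.2, 1e-6, 0.2, -np.inf], [np.inf, 1e9, 6.0, 1e9, 6.0, np.inf])
    best = _multistart_fit(biphasic_hill, c, r, sigma, starts, bounds, names)
    if best is None:
        return FitResult("biphasic_hill", dict.fromkeys(names, np.nan),
                         dict.fromkeys(names, np.nan), np.nan, len(r), np.nan, False,
                         ["no_convergence"])
    popt, pcov, rss = best
    se = np.sqrt(np.clip(np.diag(pcov), 0, None))
    result = FitResult("biphasic_hill", dict(zip(names, map(float, popt))),
                       dict(zip(names, map(float, se))), rss, len(r),
                       _aic(rss, len(r), len(names)), True)
    if result.params["ec50"] >= result.params["ic50"]:
        result.flags.append("ec50_not_below_ic50")
    try:
        single = fit_hill(table, weighted)
        if single.converged and single.aic < result.aic:
            result.flags.append("no_biphasic_evidence")
    except ValueError:
        pass
    return result


def fit_langmuir_inhibition(table: pd.DataFrame, weighted: bool = True) -> FitResult:
    """Fit the Langmuir inhibition curve; reports f0 and IC50.

    Needs >= 4 distinct concentrations.  Monotonically increasing data are
    flagged 'increasing_response'.
    """
    c, r, sigma = _extract(table, weighted)
    if len(np.unique(c)) < 4:
        raise ValueError("fit_langmuir_inhibition needs at least 4 distinct concentrations")
    names = ["f0", "ic50"]
    starts = [(float(r.max()), ic) for ic in np.geomspace(max(c[c > 0].min(), 1e-3),
                                                          max(c.max(), 1.0), 5)]
    bounds = ([0.0, 1e-6], [np.inf, 1e9])
    best = _multistart_fit(langmuir_inhibition, c, r, sigma, starts, bounds, names)
    if best is None:
        return FitResult("langmuir", dict.fromkeys(names, np.nan),
                         dict.fromkeys(names, np.nan), np.nan, len(r), np.nan, False,
                         ["no_convergence"])
    popt, pcov, rss = best
    se = np.sqrt(np.clip(np.diag(pcov), 0, None))
    result = FitResult("langmuir", dict(zip(names, map(float, popt))),
                       dict(zip(names, map(float, se))), rss, len(r),
                       _aic(rss, len(r), len(names)), True)
    order = np.argsort(c)
    slope = np.polyfit(c[order], r[order], 1)[0]
    if slope > 0:
        result.flags.append("increasing_response")
    return result


_FITTERS = {"hill": fit_hill, "biphasic_hill": fit_biphasic_hill,
            "langmuir": fit_langmuir_inhibition}
_MODELS = {"hill": hill, "biphasic_hill": biphasic_hill, "langmuir": langmuir_inhibition}


def bootstrap_se(
    table: pd.DataFrame, model: str, n_boot: int = 200, seed: int = 0,
    weighted: bool = True,
) -> dict[str, float]:
    """Residual-bootstrap standard errors for a dose-response fit.

    Refits ``n_boot`` tables with resampled residuals added back onto the
    fitted curve; returns the parameter-wise bootstrap sd.  Used as an
    independent cross-check of the covariance-based errors.
    """
    fitter, fn = _FITTERS[model], _MODELS[model]
    base = fitter(table, weighted)
    if not base.converged:
        raise ValueError("cannot bootstrap a non-converged fit")
    rng = np.random.default_rng(seed)
    c = table["concentration_nM"].to_numpy(dtype=float)
    fitted = fn(c, *base.params.values())
    resid = table["response"].to_numpy(dtype=float) - fitted
    draws: dict[str, list[float]] = {k: [] for k in base.params}
    for _ in range(n_boot):
        boot = table.copy()
        boot["response"] = fitted + rng.choice(resid, size=len(resid), replace=True)
        res = fitter(boot, weighted)
        if res.converged:
            for k, v in res.params.items():
                draws[k].append(v)
    return {k: float(np.std(v, ddof=1)) if len(v) > 2 else np.nan for k, v in draws.items()}
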