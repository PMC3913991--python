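"""Exact-fit tests, CFI, and RMSEA for all three evaluation approaches.

The simultaneous ("standard") approach compares the hypothesized two-level
model to the fully saturated one; its chi-square mixes within- and
between-level misfit with weights N - J and J.  The level-specific approach
isolates one level by saturating the other (partially saturated models,
statistics PS_B and PS_W); the segregating approach (YB_B / YB_W) evaluates
each level as a single-level model fit to the estimated unrestricted
covariance matrix for that level.

Noncentrality-based indices use the approach-appropriate effective sample
size as multiplier:

    standard   N - 1
    PS_B       J      (option: J - 1)
    PS_W       N - J  (option: N - J - 1)
    segregated n_eff - 1

and the approach-appropriate independence baseline for CFI (a partially
saturated independence model for the level-specific statistics).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .data import SufficientStatistics
from .model import (WITHIN, BETWEEN, TwoLevelModelSpec, saturate, independence,
                    count_df)
from . import estimation
from .estimation import FitResult, fit

_log = logging.getLogger(__name__)

__all__ = [
    "FitIndexReport",
    "chi2_standard",
    "chi2_level_specific",
    "cfi",
    "rmsea",
    "format_p",
    "evaluate_fit",
]

# a saturated-vs-hypothesized discrepancy more negative than this signals a
# convergence failure rather than round-off
_NEG_TOL = 1e-2


@dataclass
class FitIndexReport:
    """Chi-square test and fit indices for one approach at one scope."""

    approach: str            # standard | PS_B | PS_W | YB_B | YB_W
    chi2: float
    df: int
    p_value: float
    cfi: float
    rmsea: float
    multiplier: float
    noncentrality_hat: float
    f0_hat: float
    converged: bool = True
    status: str = "ok"
    notes: list = field(default_factory=list)

    @property
    def p_display(self) -> str:
        return format_p(self.p_value)


def format_p(p: float) -> str:
    """Render a p-value the way fit tables print it."""
    if not np.isfinite(p):
        return "NA"
    return "<0.001" if p < 0.001 else f"{p:.3f}"


# ---------------------------------------------------------------------------
# Elementary index arithmetic
# ---------------------------------------------------------------------------

def cfi(chi2_H: float, df_H: int, chi2_B: float, df_B: int) -> float:
    """Comparative fit index: 1 - max(chi2_H - df_H, 0)/max(chi2_B - df_B, 0),
    clipped to [0, 1].  The baseline must be the approach-appropriate
    independence model."""
    num = max(chi2_H - df_H, 0.0)
    den = max(chi2_B - df_B, 0.0)
    if num == 0.0:
        return 1.0
    if den <= 0.0:
        _log.warning("baseline fits better than hypothesized; CFI reported as 0")
        return 0.0
    return float(np.clip(1.0 - num / den, 0.0, 1.0))


def rmsea(chi2: float, df: int, multiplier: float) -> float:
    """Root mean squared error of approximation,
    sqrt(max((chi2 - df) / (df * multiplier), 0)).

    ``multiplier`` is the approach's effective sample-size factor (N-1 for the
    standard approach, J for PS_B, N-J for PS_W, n_eff-1 for a single-level
    fit)."""
    if df < 1:
        raise ValueError("RMSEA undefined for saturated model")
    if multiplier < 1:
        raise ValueError("multiplier must be >= 1")
    return math.sqrt(max((chi2 - df) / (df * multiplier), 0.0))


def _p_value(chi2: float, df: int) -> float:
    if df <= 0:
        return 1.0
    return float(sps.chi2.sf(chi2, df))


def _chi2_diff(f_h: float, f_s: float) -> float:
    diff = f_h - f_s
    if diff < -_NEG_TOL:
        raise ValueError(
            "saturated fit worse than hypothesized -- check convergence "
            f"(difference {diff:.4g})"
        )
    return max(diff, 0.0)


# ---------------------------------------------------------------------------
# Chi-square tests
# ---------------------------------------------------------------------------

def chi2_standard(fit_H: FitResult, fit_S: FitResult) -> tuple[float, int, float]:
    """Simultaneous likelihood-ratio test of exact fit: the difference of the
    minimized discrepancy values of the hypothesized and saturated models."""
    chi2 = _chi2_diff(fit_H.f_value, fit_S.f_value)
    df = count_df(fit_H.spec)[0] if fit_H.spec is not None else 0
    return chi2, df, _p_value(chi2, df)


def chi2_level_specific(spec: TwoLevelModelSpec, stats: SufficientStatistics,
                        level: str, fit_S: FitResult | None = None,
                        options: dict | None = None):
    """Level-specific exact-fit test via the partially saturated model.

    For ``level='between'`` the within level is saturated and the statistic
    isolates between-level misfit (PS_B); ``level='within'`` is the mirror
    image (PS_W).  Returns (chi2, df, p).
    """
    other = WITHIN if level == BETWEEN else BETWEEN
    ps_spec = saturate(spec, other)
    if fit_S is None:
        fit_S = fit(saturate(ps_spec, level), stats, options)
    fit_ps = fit(ps_spec, stats, options)
    if not fit_ps.converged:
        raise RuntimeError(f"partially saturated model ({level} structured) did not converge")
    if not fit_S.converged:
        raise RuntimeError("fully saturated model did not converge")
    chi2 = _chi2_diff(fit_ps.f_value, fit_S.f_value)
    _, df_b, df_w = count_df(spec)
    df = df_b if level == BETWEEN else df_w
    return chi2, df, _p_value(chi2, df)


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

def _multipliers(stats: SufficientStatistics, options: dict) -> dict:
    sub1 = str(options.get("rmsea_small_sample", "literal")) == "subtract_one"
    N, J = stats.N, stats.J
    return {
        "standard": N - 1,
        "PS_B": (J - 1) if sub1 else J,
        "PS_W": (N - J - 1) if sub1 else (N - J),
    }


def _make_report(approach, chi2v, df, chi2_base, df_base, multiplier,
                 converged=True) -> FitIndexReport:
    nc = max(chi2v - df, 0.0)
    return FitIndexReport(
        approach=approach,
        chi2=chi2v,
        df=df,
        p_value=_p_value(chi2v, df),
        cfi=cfi(chi2v, df, chi2_base, df_base),
        rmsea=rmsea(chi2v, df, multiplier) if df >= 1 else 0.0,
        multiplier=multiplier,
        noncentrality_hat=nc,
        f0_hat=nc / multiplier,
        converged=converged,
    )


def build_single_level_report(chi2v: float, df: int, S: np.ndarray, n_eff: int,
                              approach: str = "single",
                              converged: bool = True) -> FitIndexReport:
    """Standard single-level report; the independence baseline has the closed
    form chi2 = -(n_eff - 1) log|R| with R the correlation matrix of S."""
    p = S.shape[0]
    d = np.sqrt(np.diag(S))
    R = S / np.outer(d, d)
    sign, logdet_r = np.linalg.slogdet(R)
    if sign <= 0:
        raise ValueError("input matrix for the single-level fit is not positive definite")
    chi2_base = -(n_eff - 1) * float(logdet_r)
    df_base = p * (p - 1) // 2
    return _make_report(approach, chi2v, df, chi2_base, df_base, n_eff - 1,
                        converged=converged)


def aborted_report(approach: str, reason: str) -> FitIndexReport:
    """Placeholder report for a fit that could not be carried out."""
    nan = float("nan")
    return FitIndexReport(approach, nan, 0, nan, nan, nan, nan, nan, nan,
                          converged=False, status=reason)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def evaluate_fit(spec: TwoLevelModelSpec, stats: SufficientStatistics,
                 approaches=("standard", "level_specific", "segregating"),
                 options: dict | None = None) -> dict[str, FitIndexReport]:
    """Fit every model an approach needs and return one report per statistic.

    ``approaches`` may contain ``standard``, ``level_specific`` (producing
    PS_B and PS_W) and ``segregating`` (producing YB_B and YB_W).  Options:
    ``rmsea_small_sample`` ("literal" | "subtract_one"), ``neff_within`` /
    ``neff_between`` (segregating step-2 overrides), plus optimizer settings.
    """
    options = {**spec.options, **(options or {})}
    if stats.variable_names != spec.observed:
        stats = stats.subset(spec.observed)
    mult = _multipliers(stats, options)
    fit_opts = {k: options[k] for k in ("tolerance", "gtol", "max_iter") if k in options}
    reports: dict[str, FitIndexReport] = {}

    needs_sat = {"standard", "level_specific"} & set(approaches)
    fit_S = None
    if needs_sat:
        sat_spec = saturate(saturate(spec, WITHIN), BETWEEN)
        fit_S = fit(sat_spec, stats, fit_opts)

    if "standard" in approaches:
        try:
            fit_H = fit(spec, stats, fit_opts)
            chi2v, df, _ = chi2_standard(fit_H, fit_S)
            base_spec = independence(independence(spec, WITHIN), BETWEEN)
            fit_base = fit(base_spec, stats, fit_opts)
            chi2_b = _chi2_diff(fit_base.f_value, fit_S.f_value)
            df_b = 2 * (stats.p * (stats.p - 1) // 2)
            reports["standard"] = _make_report(
                "standard", chi2v, df, chi2_b, df_b, mult["standard"],
                converged=fit_H.converged and fit_base.converged)
        except (RuntimeError, ValueError) as err:
            reports["standard"] = aborted_report("standard", str(err))

    if "level_specific" in approaches:
        for approach, level in (("PS_B", BETWEEN), ("PS_W", WITHIN)):
            try:
                chi2v, df, _ = chi2_level_specific(spec, stats, level,
                                                   fit_S=fit_S, options=fit_opts)
                other = WITHIN if level == BETWEEN else BETWEEN
                base_spec = independence(saturate(spec, other), level)
                fit_base = fit(base_spec, stats, fit_opts)
                chi2_b = _chi2_diff(fit_base.f_value, fit_S.f_value)
                df_base = stats.p * (stats.p - 1) // 2
                reports[approach] = _make_report(
                    approach, chi2v, df, chi2_b, df_base, mult[approach],
                    converged=fit_base.converged)
            except (RuntimeError, ValueError) as err:
                reports[approach] = aborted_report(approach, str(err))

    if "segregating" in approaches:
        from . import segregate  # deferred import (segregate builds on this module)
        try:
            sat_est = segregate.step1(stats, options=fit_opts)
            rep_w, rep_b = segregate.step2(spec, sat_est, stats, options=options)
            reports["YB_W"] = rep_w
            reports["YB_B"] = rep_b
        except (RuntimeError, ValueError) as err:
            reports["YB_W"] = aborted_report("YB_W", str(err))
            reports["YB_B"] = aborted_report("YB_B", str(err))

    return reports
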