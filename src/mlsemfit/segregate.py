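"""Two-step segregating evaluation of a two-level model.

Step 1 estimates the unrestricted level-1 and level-2 covariance matrices
(and their asymptotic covariances) by full two-level maximum likelihood.
Step 2 treats those estimates as observed covariance matrices and evaluates
the hypothesized within and between models as two independent single-level
SEMs.  The effective sample sizes default to N - J + 1 for the within model
(chi-square multiplier N - J) and J for the between model (multiplier J - 1),
both overridable; these reproduce the near-identity of the segregated within
statistic with its level-specific counterpart on large samples.

Parameter estimates from segregated fits are computed but are not recommended
for inference; estimates should come from the full two-level model.
"""

from __future__ import annotations

import logging

import numpy as np

from .data import SufficientStatistics
from .estimation import SaturatedEstimates, fit_saturated, fit_single_level
from .indices import FitIndexReport, aborted_report
from .model import TwoLevelModelSpec

_log = logging.getLogger(__name__)

__all__ = ["step1", "step2"]

_NOT_FOR_INFERENCE = "parameter estimates from segregated fits are not recommended for inference"


def step1(stats: SufficientStatistics, options: dict | None = None) -> SaturatedEstimates:
    """Saturated two-level estimation: mu, Sigma_W, Sigma_B and the
    p(p+1)/2-dimensional asymptotic covariance matrix of each vech block.

    A non-positive-semi-definite between estimate is flagged in the bundle's
    warnings, not rejected."""
    est = fit_saturated(stats, options=options)
    if not est.sigma_b_psd:
        _log.warning("step 1: %s", est.warnings[0])
    return est


def step2(spec: TwoLevelModelSpec, sat: SaturatedEstimates,
          stats: SufficientStatistics,
          options: dict | None = None) -> tuple[FitIndexReport, FitIndexReport]:
    """Independent single-level evaluations of the within and between models.

    Returns ``(report_YB_W, report_YB_B)``.  If the between estimate is not
    positive definite the between fit is aborted with a diagnostic report
    rather than fabricated numbers."""
    options = dict(options or {})
    if stats.variable_names != spec.observed:
        stats = stats.subset(spec.observed)
    n_eff_w = int(options.get("neff_within", stats.N - stats.J + 1))
    n_eff_b = int(options.get("neff_between", stats.J))
    fit_opts = {k: options[k] for k in ("tolerance", "gtol", "max_iter") if k in options}

    fr_w, rep_w = fit_single_level(spec.within, sat.sigma_w_hat, n_eff_w,
                                   options=fit_opts, approach="YB_W")
    rep_w.notes.append(_NOT_FOR_INFERENCE)
    rep_w.converged = fr_w.converged

    eigs = np.linalg.eigvalsh((sat.sigma_b_hat + sat.sigma_b_hat.T) / 2.0)
    if eigs.min() <= 0:
        rep_b = aborted_report(
            "YB_B",
            "estimated between covariance matrix is not positive definite; "
            "the between-level single-level fit was aborted (flag-and-report)",
        )
    else:
        fr_b, rep_b = fit_single_level(spec.between, sat.sigma_b_hat, n_eff_b,
                                       options=fit_opts, approach="YB_B")
        rep_b.notes.append(_NOT_FOR_INFERENCE)
        rep_b.converged = fr_b.converged
    return rep_w, rep_b
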