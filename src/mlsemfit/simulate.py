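"""Two-level data generation and Monte-Carlo replication studies.

Data follow the two-level decomposition y_ij = mu + y_Bj + y_Wij with
independent cluster-level and unit-level random components, so that the total
covariance is Sigma_B + Sigma_W and the covariance of cluster means is
Sigma_B + Sigma_W / n_j.  Components are multivariate normal by default;
targeted marginal skewness and excess kurtosis are produced per level with
Fleishman third-order polynomials combined through Vale-Maurelli intermediate
correlations.

The ``timss_like`` preset emulates a five-variable two-level path model of
mathematics motivation, gender, and achievement measured on 5928 students in
164 schools.  Its structural paths are set to published two-level estimates;
the residual variances and covariances are fixture choices (not published
values) picked once to give intraclass correlations near 0.2 for gender and
the motivation composites, a realistic share of school-level variance for
this kind of educational survey.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .data import TwoLevelDataset, compute_sufficient_stats
from .model import TwoLevelModelSpec, parse_model

_log = logging.getLogger(__name__)

__all__ = [
    "SimulationDesign",
    "fleishman_coefficients",
    "generate",
    "simulation_study",
    "timss_like_spec",
    "timss_like_truth",
    "timss_like_design",
    "TIMSS_LIKE_PATHS",
    "TIMSS_SCORE_SD",
]


# ---------------------------------------------------------------------------
# Non-normal margins
# ---------------------------------------------------------------------------

def fleishman_coefficients(skew: float, exkurt: float) -> tuple[float, float, float, float]:
    """Coefficients (a, b, c, d) of Y = a + bZ + cZ^2 + dZ^3 giving mean 0,
    variance 1, and the target skewness / excess kurtosis.

    Raises if the moment pair is infeasible (roughly, excess kurtosis must
    exceed skewness^2 - 2, and lie in the polynomial's attainable region).
    """
    if exkurt < skew ** 2 - 2:
        raise ValueError(
            f"infeasible moments: excess kurtosis {exkurt} < skewness^2 - 2 "
            f"= {skew ** 2 - 2}"
        )

    def equations(x):
        b, c, d = x
        f1 = b ** 2 + 6 * b * d + 2 * c ** 2 + 15 * d ** 2 - 1.0
        f2 = 2 * c * (b ** 2 + 24 * b * d + 105 * d ** 2 + 2) - skew
        f3 = 24 * (b * d + c ** 2 * (1 + b ** 2 + 28 * b * d)
                   + d ** 2 * (12 + 48 * b * d + 141 * c ** 2 + 225 * d ** 2)) - exkurt
        return [f1, f2, f3]

    x0 = np.array([1.0, 0.1 * np.sign(skew) if skew else 0.0, 0.01])
    sol, info, ier, msg = optimize.fsolve(equations, x0, full_output=True)
    if ier != 1 or np.max(np.abs(equations(sol))) > 1e-9:
        raise ValueError(
            f"no Fleishman solution for skewness={skew}, excess kurtosis={exkurt}: {msg}"
        )
    b, c, d = sol
    return (-c, float(b), float(c), float(d))


def _vale_maurelli_rho(target: float, c1, c2) -> float:
    """Intermediate normal correlation whose polynomial transform attains the
    target correlation."""
    _, b1, cc1, d1 = c1
    _, b2, cc2, d2 = c2
    coef = [6 * d1 * d2, 2 * cc1 * cc2,
            b1 * b2 + 3 * b1 * d2 + 3 * d1 * b2 + 9 * d1 * d2, -target]
    roots = np.roots(coef)
    real = roots[np.abs(roots.imag) < 1e-8].real
    ok = real[(real >= -1.0) & (real <= 1.0)]
    if len(ok) == 0:
        raise ValueError(f"no intermediate correlation for target {target}")
    return float(ok[np.argmin(np.abs(ok - target))])


def _psd_factor(M: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh((M + M.T) / 2.0)
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w)


def _draw_components(n_draws: int, sigma: np.ndarray, dist, rng) -> np.ndarray:
    """Draw n_draws rows with covariance ``sigma``; ``dist`` is None/'normal'
    or a (skewness, excess kurtosis) pair applied to every margin."""
    p = sigma.shape[0]
    sd = np.sqrt(np.clip(np.diag(sigma), 0.0, None))
    if not np.any(sd > 0):
        return np.zeros((n_draws, p))
    if dist is None or dist == "normal":
        Z = rng.standard_normal((n_draws, p))
        return Z @ _psd_factor(sigma).T
    skew, exkurt = dist
    coefs = fleishman_coefficients(skew, exkurt)
    live = sd > 0
    R = np.eye(p)
    idx = np.flatnonzero(live)
    for a_ in idx:
        for b_ in idx:
            if a_ < b_:
                r = sigma[a_, b_] / (sd[a_] * sd[b_])
                R[a_, b_] = R[b_, a_] = _vale_maurelli_rho(r, coefs, coefs)
    Z = rng.standard_normal((n_draws, p)) @ _psd_factor(R).T
    a, b, c, d = coefs
    Y = a + b * Z + c * Z ** 2 + d * Z ** 3
    return Y * sd


# ---------------------------------------------------------------------------
# Design and generation
# ---------------------------------------------------------------------------

@dataclass
class SimulationDesign:
    """Generating conditions for one two-level simulation cell.

    ``cluster_sizes`` is a constant int, an explicit length-J vector, or a
    mapping {"kind": "uniform", "low": .., "high": .., "total": optional}
    drawn inside the seeded stream (with ``total`` the draw is adjusted to
    sum exactly to it).
    """

    sigma_b: np.ndarray
    sigma_w: np.ndarray
    mu: np.ndarray
    J: int
    cluster_sizes: object
    dist_within: object = None
    dist_between: object = None
    seed: int = 0
    replications: int = 1
    variable_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sigma_b = np.asarray(self.sigma_b, dtype=float)
        self.sigma_w = np.asarray(self.sigma_w, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        p = len(self.mu)
        if self.sigma_b.shape != (p, p) or self.sigma_w.shape != (p, p):
            raise ValueError("sigma_b/sigma_w dimensions do not match mu")
        if np.linalg.eigvalsh(self.sigma_w).min() <= 0:
            raise ValueError("generating Sigma_W must be positive definite")
        if np.linalg.eigvalsh(self.sigma_b).min() < -1e-12:
            raise ValueError("generating Sigma_B must be positive semi-definite")
        if not self.variable_names:
            self.variable_names = [f"y{k + 1}" for k in range(p)]
        # fail before any sampling on infeasible moment targets
        for dist in (self.dist_within, self.dist_between):
            if dist is not None and dist != "normal":
                fleishman_coefficients(*dist)


def _sizes_with_total(J: int, low: int, high: int, total: int, rng) -> np.ndarray:
    if not (J * low <= total <= J * high):
        raise ValueError(f"total {total} unreachable with {J} clusters in [{low}, {high}]")
    sizes = rng.integers(low, high + 1, size=J)
    diff = int(total - sizes.sum())
    while diff != 0:
        step = 1 if diff > 0 else -1
        cand = np.flatnonzero((sizes + step >= low) & (sizes + step <= high))
        k = int(rng.choice(cand))
        sizes[k] += step
        diff -= step
    return sizes


def _resolve_sizes(design: SimulationDesign, rng) -> np.ndarray:
    cs = design.cluster_sizes
    if isinstance(cs, (int, np.integer)):
        return np.full(design.J, int(cs), dtype=int)
    if isinstance(cs, dict):
        low, high = int(cs["low"]), int(cs["high"])
        total = cs.get("total")
        if total is None:
            return rng.integers(low, high + 1, size=design.J)
        return _sizes_with_total(design.J, low, high, int(total), rng)
    sizes = np.asarray(cs, dtype=int)
    if len(sizes) != design.J:
        raise ValueError("explicit cluster size vector must have length J")
    return sizes


def generate(design: SimulationDesign, rng=None) -> TwoLevelDataset:
    """Generate one two-level dataset: one between draw per cluster, one
    within draw per unit, summed with mu.  Fully reproducible from the seed;
    pass ``rng`` to place the draw inside an external seeded stream."""
    if rng is None:
        rng = np.random.default_rng(design.seed)
    sizes = _resolve_sizes(design, rng)
    N = int(sizes.sum())
    yb = _draw_components(design.J, design.sigma_b, design.dist_between, rng)
    yw = _draw_components(N, design.sigma_w, design.dist_within, rng)
    cluster = np.repeat(np.arange(design.J), sizes)
    values = design.mu + yb[cluster] + yw
    return TwoLevelDataset(values=values, cluster_id=cluster,
                           variable_names=list(design.variable_names))


# ---------------------------------------------------------------------------
# Replication studies
# ---------------------------------------------------------------------------

def simulation_study(design: SimulationDesign, specs_to_fit: dict,
                     approaches=("standard", "level_specific"),
                     alpha: float = 0.05,
                     options: dict | None = None,
                     return_records: bool = False):
    """Run ``design.replications`` independent replications, fit every spec in
    ``specs_to_fit`` (name -> TwoLevelModelSpec) with every approach, and
    summarize rejection rates at ``alpha`` plus index distributions.

    Non-converged replications are excluded from the summaries and counted in
    the ``n_failed`` column.  Per-replication child seeds are spawned from
    ``design.seed`` and logged at debug level.
    """
    ss = np.random.SeedSequence(design.seed)
    children = ss.spawn(design.replications)
    records = []
    for r, child in enumerate(children):
        rng = np.random.default_rng(child)
        _log.debug("replication %d seed %s", r, child.entropy)
        data = generate(design, rng=rng)
        stats = compute_sufficient_stats(data)
        for name, spec in specs_to_fit.items():
            try:
                reports = _evaluate(spec, stats, approaches, options)
            except (RuntimeError, ValueError) as err:
                _log.warning("replication %d spec %s failed: %s", r, name, err)
                records.append({"rep": r, "spec": name, "approach": "all",
                                "failed": True})
                continue
            for approach, rep in reports.items():
                records.append({
                    "rep": r, "spec": name, "approach": approach,
                    "failed": not rep.converged or not np.isfinite(rep.chi2),
                    "chi2": rep.chi2, "df": rep.df, "p": rep.p_value,
                    "cfi": rep.cfi, "rmsea": rep.rmsea,
                })
    rec = pd.DataFrame.from_records(records)
    rows = []
    for (name, approach), grp in rec.groupby(["spec", "approach"]):
        ok = grp[~grp["failed"].astype(bool)]
        n_ok = len(ok)
        row = {"spec": name, "approach": approach,
               "n_reps": len(grp), "n_failed": len(grp) - n_ok}
        if n_ok and "chi2" in ok:
            row.update({
                "reject_rate": float((ok["p"] < alpha).mean()),
                "mean_chi2": float(ok["chi2"].mean()),
                "q05_chi2": float(ok["chi2"].quantile(0.05)),
                "q95_chi2": float(ok["chi2"].quantile(0.95)),
                "mean_df": float(ok["df"].mean()),
                "mean_cfi": float(ok["cfi"].mean()),
                "mean_rmsea": float(ok["rmsea"].mean()),
            })
        rows.append(row)
    summary = pd.DataFrame(rows)
    if return_records:
        return summary, rec
    return summary


def _evaluate(spec, stats, approaches, options):
    from .indices import evaluate_fit  # deferred to keep import graph simple
    return evaluate_fit(spec, stats, approaches=approaches, options=options)


# ---------------------------------------------------------------------------
# TIMSS-like preset
# ---------------------------------------------------------------------------

TIMSS_VARS = ["Female", "MConf", "MUtil", "MInt", "MAch"]
TIMSS_SCORE_SD = 10.0  # national math score scale: mean 150, SD 10

# published two-level path estimates used as generating values
TIMSS_LIKE_PATHS = {
    "within": {
        ("MConf", "Female"): 0.165,
        ("MInt", "Female"): 0.052,
        ("MAch", "MConf"): -2.929,
        ("MAch", "MUtil"): -0.909,
        ("MAch", "MInt"): -0.558,
        ("MAch", "Female"): 0.957,
    },
    "between": {
        ("MConf", "Female"): 0.056,
        ("MInt", "Female"): 0.069,
        ("MAch", "MConf"): -36.850,
        ("MAch", "MUtil"): 7.460,
        ("MAch", "MInt"): 13.455,
        ("MAch", "Female"): 6.844,
    },
}

# fixture choices (not published values): exogenous/residual variances and
# covariances giving intraclass correlations near 0.2 for gender and the
# motivation composites
_TIMSS_S = {
    "within": {
        ("Female", "Female"): 0.25,
        ("MConf", "MConf"): 0.55,
        ("MUtil", "MUtil"): 0.60,
        ("MInt", "MInt"): 0.60,
        ("MConf", "MUtil"): 0.25,
        ("MConf", "MInt"): 0.28,
        ("MUtil", "MInt"): 0.30,
        ("MAch", "MAch"): 66.0,
    },
    "between": {
        ("Female", "Female"): 0.0625,
        ("MConf", "MConf"): 0.14,
        ("MUtil", "MUtil"): 0.15,
        ("MInt", "MInt"): 0.15,
        ("MConf", "MUtil"): 0.105,
        ("MConf", "MInt"): 0.11,
        ("MUtil", "MInt"): 0.12,
        ("MAch", "MAch"): 6.0,
    },
}

_TIMSS_MU = np.array([0.5, 2.0, 2.1, 2.2, 150.0])

TIMSS_MODEL_CONFIG = """
variables: [Female, MConf, MUtil, MInt, MAch]
within: |
  MConf ~ Female
  MInt  ~ Female
  MAch  ~ MConf + MUtil + MInt + Female
  MConf ~~ MUtil
  MConf ~~ MInt
  MUtil ~~ MInt
between: |
  MConf ~ Female
  MInt  ~ Female
  MAch  ~ MConf + MUtil + MInt + Female
  MConf ~~ MUtil
  MConf ~~ MInt
  MUtil ~~ MInt
"""


def timss_like_spec(drop_within_conf: bool = False,
                    drop_between_female: bool = False) -> TwoLevelModelSpec:
    """The hypothesized two-level path model of motivation, gender, and
    achievement (df 1 at each level).

    ``drop_within_conf`` fixes the within-level confidence -> achievement
    path to zero (a within-level misspecification, df 2 at level 1);
    ``drop_between_female`` fixes the between-level gender-composition ->
    achievement path to zero (a between-level misspecification, df 2 at
    level 2).
    """
    cfg = TIMSS_MODEL_CONFIG
    if drop_within_conf:
        head, _, tail = cfg.partition("within: |")
        tail = tail.replace("MAch  ~ MConf", "MAch  ~ fix(0)*MConf", 1)
        cfg = head + "within: |" + tail
    if drop_between_female:
        head, _, tail = cfg.partition("between: |")
        tail = tail.replace("MInt + Female", "MInt + fix(0)*Female", 1)
        cfg = head + "between: |" + tail
    return parse_model(cfg)


def _level_sigma(level: str) -> np.ndarray:
    names = TIMSS_VARS
    p = len(names)
    idx = {v: k for k, v in enumerate(names)}
    A = np.zeros((p, p))
    for (dep, pred), v in TIMSS_LIKE_PATHS[level].items():
        A[idx[dep], idx[pred]] = v
    S = np.zeros((p, p))
    for (a, b), v in _TIMSS_S[level].items():
        S[idx[a], idx[b]] = v
        S[idx[b], idx[a]] = v
    B = np.linalg.solve(np.eye(p) - A, np.eye(p))
    sigma = B @ S @ B.T
    return (sigma + sigma.T) / 2.0


def timss_like_truth() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generating (Sigma_B, Sigma_W, mu) of the TIMSS-like fixture."""
    return _level_sigma("between"), _level_sigma("within"), _TIMSS_MU.copy()


MEDIATION_MODEL_CONFIG = """
variables: [x, med, y]
within: |
  med ~ x
  y ~ med
between: |
  med ~ x
  y ~ med
"""


def mediation_spec() -> TwoLevelModelSpec:
    """Three-variable mediation chain x -> med -> y at both levels
    (df 1 per level); the direct x -> y path is correctly absent."""
    return parse_model(MEDIATION_MODEL_CONFIG)


def mediation_truth() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generating (Sigma_B, Sigma_W, mu) for the mediation design: unit
    within variances, paths 0.5 and 0.6, and a between level that is the
    within structure scaled to intraclass correlation 0.2."""
    a, b = 0.5, 0.6
    sigma_w = np.array([
        [1.0, a, a * b],
        [a, 1.0, b],
        [a * b, b, 1.0],
    ])
    sigma_b = 0.25 * sigma_w
    return sigma_b, sigma_w, np.zeros(3)


def mediation_design(seed: int = 0, J: int = 200, n: int = 10,
                     replications: int = 1) -> SimulationDesign:
    sigma_b, sigma_w, mu = mediation_truth()
    return SimulationDesign(
        sigma_b=sigma_b, sigma_w=sigma_w, mu=mu, J=J, cluster_sizes=n,
        seed=seed, replications=replications,
        variable_names=["x", "med", "y"],
    )


def timss_like_design(seed: int = 0, J: int = 164, balanced: bool = True,
                      replications: int = 1) -> SimulationDesign:
    """TIMSS-like simulation design: J = 164 schools of 36 students when
    ``balanced`` (the fixture's simulation conditions), otherwise school
    sizes drawn from 26..42 adjusted to total exactly 5928 students (the
    empirical dimensions)."""
    sigma_b, sigma_w, mu = timss_like_truth()
    sizes = 36 if balanced else {"kind": "uniform", "low": 26, "high": 42,
                                 "total": 5928}
    return SimulationDesign(
        sigma_b=sigma_b, sigma_w=sigma_w, mu=mu, J=J, cluster_sizes=sizes,
        seed=seed, replications=replications, variable_names=list(TIMSS_VARS),
    )
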