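"""Maximum-likelihood estimation for two-level covariance structure models.

The ML discrepancy for a two-level model with level-2 (between) covariance
Sigma_B and level-1 (within) covariance Sigma_W is

    F = sum_j [ log|Sigma_gj| + tr(Sigma_gj^{-1} S_Bj) ]
        + sum_j (n_j - 1) [ log|Sigma_W| + tr(Sigma_W^{-1} S_Wj) ]

with Sigma_gj = Sigma_W + n_j Sigma_B.  Because Sigma_gj depends on cluster
size only, the sums collapse to one term per distinct cluster size plus a
single pooled within term, which is what this module evaluates.  The exact
log-likelihood (including the normal constants) differs from -F/2 by
N p log(2*pi)/2 when the mean is held at the grand mean, and by the profiled
mean term otherwise; both are available.

Free parameters live on the raw scale.  Within-level covariance matrices must
be positive definite (a barrier value is returned outside the feasible
region); the between matrix is deliberately allowed to be indefinite so that
the unrestricted (saturated) between estimate can go where the likelihood
takes it -- forcing it positive would change the level-specific chi-squares.

Analytic gradients follow the chain rule through the RAM structure: with
B = (I - A)^{-1} and dF = tr(W_W dSigma_W) + tr(W_B dSigma_B), the gradient
for an S entry is read off B' F' W F B and for an A entry off
(B S B') F' W F B.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .data import SufficientStatistics
from .model import WITHIN, BETWEEN, LevelModel, TwoLevelModelSpec, saturate

_log = logging.getLogger(__name__)

__all__ = [
    "FitResult",
    "SaturatedEstimates",
    "log_likelihood",
    "f_ml",
    "fit",
    "fit_saturated",
    "fit_single_level",
]

_BIG = 1e15
_LOG2PI = float(np.log(2.0 * np.pi))

DEFAULT_OPTIONS = {
    "tolerance": 1e-12,   # relative function-decrease tolerance
    "gtol": None,         # projected-gradient tolerance; None = 1e-7*(1+|F0|)
    "max_iter": 500,
}


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """One fitted model: estimates, likelihood, convergence diagnostics."""

    theta_hat: dict
    minus2ll: float
    f_value: float
    converged: bool
    n_iter: int
    gradient_norm: float
    spec: TwoLevelModelSpec | None
    stats_ref: SufficientStatistics | None
    sigma_w: np.ndarray | None = None
    sigma_b: np.ndarray | None = None
    mu_hat: np.ndarray | None = None
    message: str = ""


@dataclass
class SaturatedEstimates:
    """Unrestricted two-level ML estimates and their asymptotic covariances."""

    mu_hat: np.ndarray
    sigma_w_hat: np.ndarray
    sigma_b_hat: np.ndarray
    acov_w: np.ndarray
    acov_b: np.ndarray
    minus2ll: float
    f_value: float
    sigma_b_psd: bool = True
    warnings: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Discrepancy evaluation
# ---------------------------------------------------------------------------

def _chol_logdet_inv(M: np.ndarray):
    """(logdet, inverse) via Cholesky; None if not positive definite."""
    try:
        L = np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        return None
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    inv = np.linalg.inv(L)
    return logdet, inv.T @ inv


class _Discrepancy:
    """Grouped evaluation of the two-level ML discrepancy and its weights."""

    def __init__(self, stats: SufficientStatistics):
        self.stats = stats
        self.p = stats.p
        self.N = stats.N
        self.J = stats.J
        self.ybar = stats.grand_mean
        self.S_pw = stats.pooled_within
        # per distinct cluster size: (n, J_n, group mean of cluster means,
        # scatter of cluster means around that group mean)
        self.groups = []
        for n in np.unique(stats.n_j):
            mask = stats.n_j == n
            means = stats.cluster_means[mask]
            m_g = means.mean(axis=0)
            dev = means - m_g
            self.groups.append((int(n), int(mask.sum()), m_g, dev.T @ dev))

    def s_b_group(self, n, J_n, m_g, scatter, mu) -> np.ndarray:
        """Group average of S_Bj = n (ybar_j - mu)(ybar_j - mu)'."""
        d = (m_g - mu)[:, None]
        return (n / J_n) * (scatter + J_n * (d @ d.T))

    def value(self, sigma_b, sigma_w, mu=None, weights=False):
        """Discrepancy F (Eq-style, centered at ``mu``; grand mean if None).

        With ``weights=True`` also returns (W_B, W_W, grad_mu) such that
        dF = tr(W_B dSigma_B) + tr(W_W dSigma_W) + grad_mu' dmu.
        Returns None when a required matrix is not positive definite.
        """
        if mu is None:
            mu = self.ybar
        cw = _chol_logdet_inv(sigma_w)
        if cw is None:
            return None
        logdet_w, inv_w = cw
        nw = self.N - self.J
        F = nw * (logdet_w + float(np.sum(inv_w * self.S_pw)))
        W_W = nw * (inv_w - inv_w @ self.S_pw @ inv_w) if weights else None
        W_B = np.zeros_like(sigma_w) if weights else None
        grad_mu = np.zeros(self.p) if weights else None
        for n, J_n, m_g, scatter in self.groups:
            cg = _chol_logdet_inv(sigma_w + n * sigma_b)
            if cg is None:
                return None
            logdet_g, inv_g = cg
            S_bg = self.s_b_group(n, J_n, m_g, scatter, mu)
            F += J_n * (logdet_g + float(np.sum(inv_g * S_bg)))
            if weights:
                Wg = J_n * (inv_g - inv_g @ S_bg @ inv_g)
                W_W = W_W + Wg
                W_B = W_B + n * Wg
                grad_mu -= 2.0 * n * J_n * (inv_g @ (m_g - mu))
        if weights:
            return F, W_B, W_W, grad_mu
        return F

    def profiled_mu(self, sigma_b, sigma_w) -> np.ndarray:
        """GLS mean that maximizes the likelihood at fixed covariances."""
        A = np.zeros((self.p, self.p))
        b = np.zeros(self.p)
        for n, J_n, m_g, _ in self.groups:
            cg = _chol_logdet_inv(sigma_w + n * sigma_b)
            if cg is None:
                raise ValueError("infeasible parameter point (Sigma_gj not PD)")
            inv_g = cg[1]
            A += n * J_n * inv_g
            b += n * J_n * (inv_g @ m_g)
        return np.linalg.solve(A, b)

    def minus2ll(self, sigma_b, sigma_w, mu=None) -> float:
        """-2 log-likelihood (full constants) at ``mu`` (profiled if None)."""
        if mu is None:
            mu = self.profiled_mu(sigma_b, sigma_w)
        F = self.value(sigma_b, sigma_w, mu=mu)
        if F is None:
            raise ValueError("infeasible parameter point (covariance not PD)")
        return F + self.N * self.p * _LOG2PI


# ---------------------------------------------------------------------------
# Parameter mapping
# ---------------------------------------------------------------------------

class _ParamMap:
    """Maps a flat theta vector onto both levels' (A, S) matrices.

    Labels are deduplicated across levels: auto labels get a level prefix
    (never shared), user labels are shared verbatim.
    """

    def __init__(self, spec: TwoLevelModelSpec):
        self.spec = spec
        self.labels: list[str] = []
        self.slots: list[list[tuple[str, str, int, int]]] = []
        index: dict[str, int] = {}
        for lvl, lm, prefix in ((WITHIN, spec.within, "w"), (BETWEEN, spec.between, "b")):
            for slot in lm.free_slots():
                user = lm.labels.get(slot)
                lab = user if user is not None else f"{prefix}:{lm._auto_label(slot)}"
                if lab not in index:
                    index[lab] = len(self.labels)
                    self.labels.append(lab)
                    self.slots.append([])
                self.slots[index[lab]].append((lvl,) + slot)

    @property
    def k(self) -> int:
        return len(self.labels)

    def matrices(self, theta):
        A = {WITHIN: self.spec.within.a_value.copy(), BETWEEN: self.spec.between.a_value.copy()}
        S = {WITHIN: self.spec.within.s_value.copy(), BETWEEN: self.spec.between.s_value.copy()}
        for v, slots in zip(theta, self.slots):
            for lvl, mat, i, j in slots:
                if mat == "A":
                    A[lvl][i, j] = v
                else:
                    S[lvl][i, j] = v
                    S[lvl][j, i] = v
        return A, S

    def gather_gradient(self, grads: dict) -> np.ndarray:
        """Sum per-slot gradient contributions into theta order.

        ``grads[(lvl, mat)]`` holds the full-matrix gradient arrays: for S the
        matrix G_S with dF/dS_ij = G_S[i,j] (i == j) or 2 G_S[i,j] (i != j);
        for A the matrix X with dF/dA_ij = 2 X[j, i].
        """
        g = np.zeros(self.k)
        for idx, slots in enumerate(self.slots):
            for lvl, mat, i, j in slots:
                if mat == "A":
                    g[idx] += 2.0 * grads[(lvl, "A")][j, i]
                elif i == j:
                    g[idx] += grads[(lvl, "S")][i, i]
                else:
                    g[idx] += 2.0 * grads[(lvl, "S")][i, j]
        return g


def _level_sigma_and_cache(lm: LevelModel, A: np.ndarray, S: np.ndarray):
    I = np.eye(lm.m)
    try:
        B = np.linalg.solve(I - A, I)
    except np.linalg.LinAlgError as err:
        raise ValueError("non-recursive or ill-specified path matrix") from err
    full = B @ S @ B.T
    idx = lm.observed_idx
    sigma = full[np.ix_(idx, idx)]
    return (sigma + sigma.T) / 2.0, B, S


def _level_grads(lm: LevelModel, B: np.ndarray, S: np.ndarray, W: np.ndarray):
    """Full-matrix gradient arrays for one level given weight matrix W."""
    m = lm.m
    W_full = np.zeros((m, m))
    idx = lm.observed_idx
    W_full[np.ix_(idx, idx)] = W
    T = B.T @ W_full @ B                     # S-entry gradients
    X = (B @ S @ B.T) @ W_full @ B           # A-entry gradients via X[j, i]
    return T, X


# ---------------------------------------------------------------------------
# Public evaluation wrappers
# ---------------------------------------------------------------------------

def _implied(spec: TwoLevelModelSpec, theta) -> tuple[np.ndarray, np.ndarray]:
    pm = _ParamMap(spec)
    A, S = pm.matrices(np.asarray(theta, dtype=float))
    sw, _, _ = _level_sigma_and_cache(spec.within, A[WITHIN], S[WITHIN])
    sb, _, _ = _level_sigma_and_cache(spec.between, A[BETWEEN], S[BETWEEN])
    return sb, sw


def f_ml(spec: TwoLevelModelSpec, theta, stats: SufficientStatistics) -> float:
    """Two-level ML discrepancy at ``theta`` (flat vector over both levels,
    in :class:`_ParamMap` label order; see :func:`fit` result ``theta_hat``)."""
    stats = stats.subset(spec.observed) if stats.variable_names != spec.observed else stats
    sb, sw = _implied(spec, theta)
    F = _Discrepancy(stats).value(sb, sw)
    if F is None:
        raise ValueError("infeasible parameter point (covariance not PD)")
    return F


def log_likelihood(spec: TwoLevelModelSpec, theta, stats: SufficientStatistics,
                   mu=None) -> float:
    """Exact two-level log-likelihood at ``theta``; the mean is profiled out
    unless ``mu`` is given."""
    stats = stats.subset(spec.observed) if stats.variable_names != spec.observed else stats
    sb, sw = _implied(spec, theta)
    return -0.5 * _Discrepancy(stats).minus2ll(sb, sw, mu=mu)


# ---------------------------------------------------------------------------
# Starting values
# ---------------------------------------------------------------------------

def _psd_clamp(M: np.ndarray, floor: float) -> np.ndarray:
    w, V = np.linalg.eigh((M + M.T) / 2.0)
    return V @ np.diag(np.maximum(w, floor)) @ V.T


def _level_start_target(stats: SufficientStatistics, lvl: str) -> np.ndarray:
    """Observed analog of the level covariance used to seed starting values."""
    if lvl == WITHIN:
        return stats.pooled_within
    nbar = stats.N / stats.J
    return (stats.mean_S_B() - stats.pooled_within) / nbar


def _default_start(pm: _ParamMap, stats: SufficientStatistics) -> np.ndarray:
    spec = pm.spec
    targets = {lvl: _level_start_target(stats, lvl) for lvl in (WITHIN, BETWEEN)}
    floor = {
        WITHIN: 1e-4 * float(np.mean(np.diag(targets[WITHIN]))),
        BETWEEN: 1e-4 * float(np.mean(np.diag(targets[WITHIN]))) / (stats.N / stats.J),
    }
    safe = {lvl: _psd_clamp(targets[lvl], floor[lvl]) for lvl in (WITHIN, BETWEEN)}
    # per-equation OLS path starts from the safe target matrices
    path_start: dict[tuple, float] = {}
    resid_start: dict[tuple, float] = {}
    for lvl, lm in ((WITHIN, spec.within), (BETWEEN, spec.between)):
        C = safe[lvl]
        obs_pos = {v: k for k, v in enumerate(lm.observed)}
        for i in range(lm.m):
            preds = [j for j in range(lm.m) if lm.a_free[i, j]]
            name_i = lm.names[i]
            if name_i not in obs_pos or any(lm.names[j] not in obs_pos for j in preds):
                continue
            if not preds:
                continue
            pi = obs_pos[name_i]
            pj = [obs_pos[lm.names[j]] for j in preds]
            Cpp = C[np.ix_(pj, pj)]
            try:
                b = np.linalg.solve(Cpp, C[pj, pi])
            except np.linalg.LinAlgError:
                continue
            for j, bj in zip(preds, b):
                path_start[(lvl, "A", i, j)] = float(bj)
            rv = float(C[pi, pi] - b @ C[pj, pi])
            resid_start[(lvl, "S", i, i)] = max(rv, 0.05 * float(C[pi, pi]))

    x0 = np.zeros(pm.k)
    for idx, slots in enumerate(pm.slots):
        lvl, mat, i, j = slots[0]
        lm = spec.level(lvl)
        C = safe[lvl] if not lm.is_saturated else targets[lvl]
        obs_pos = {v: k for k, v in enumerate(lm.observed)}
        key = (lvl, mat, i, j)
        if mat == "A":
            if key in path_start:
                x0[idx] = path_start[key]
            elif lm.names[j] not in obs_pos:   # factor loading
                x0[idx] = 0.7
        else:
            ni, nj = lm.names[i], lm.names[j]
            if i == j:
                if ni in obs_pos:
                    pi = obs_pos[ni]
                    x0[idx] = resid_start.get(key, float(C[pi, pi]))
                    if x0[idx] <= 0:
                        x0[idx] = max(float(C[pi, pi]), floor[lvl])
                else:
                    x0[idx] = 1.0
            elif lm.is_saturated and ni in obs_pos and nj in obs_pos:
                x0[idx] = float(C[obs_pos[ni], obs_pos[nj]])
    return x0


def _param_scales(pm: _ParamMap, stats: SufficientStatistics) -> np.ndarray:
    """Typical magnitude per free parameter, from the level target matrices:
    sqrt(C_ii C_jj) for an (i, j) covariance entry, sqrt(C_ii / C_jj) for a
    path j -> i, and 1 for latent-variable entries."""
    spec = pm.spec
    diag = {}
    for lvl in (WITHIN, BETWEEN):
        d = np.abs(np.diag(_level_start_target(stats, lvl)))
        floor = 1e-3 * max(float(d.max()), 1e-12)
        diag[lvl] = np.maximum(d, floor)
    s = np.ones(pm.k)
    for idx, slots in enumerate(pm.slots):
        lvl, mat, i, j = slots[0]
        lm = spec.level(lvl)
        obs_pos = {v: k for k, v in enumerate(lm.observed)}
        ni, nj = lm.names[i], lm.names[j]
        di = diag[lvl][obs_pos[ni]] if ni in obs_pos else 1.0
        dj = diag[lvl][obs_pos[nj]] if nj in obs_pos else 1.0
        s[idx] = np.sqrt(di / dj) if mat == "A" else np.sqrt(di * dj)
    return s


# ---------------------------------------------------------------------------
# Core fitting
# ---------------------------------------------------------------------------

def _minimize(fun, x0, options, scales=None):
    """L-BFGS-B in coordinates whitened by ``scales`` (per-parameter typical
    magnitudes), which keeps mixed-scale problems -- a test-score variance of
    70 next to a binary-indicator variance of 0.25 -- well conditioned."""
    opts = dict(DEFAULT_OPTIONS)
    opts.update(options or {})
    if scales is None:
        scales = np.ones_like(x0)
    s = np.asarray(scales, dtype=float)

    def zfun(z):
        f, g = fun(z * s)
        return f, g * s

    def hessp(z, v):
        h = 1e-7 * max(1.0, float(np.linalg.norm(z))) / max(float(np.linalg.norm(v)), 1e-12)
        return (zfun(z + h * v)[1] - zfun(z - h * v)[1]) / (2.0 * h)

    z0 = x0 / s
    f0 = zfun(z0)[0]
    gtol = opts.get("gtol") or 1e-7 * (1.0 + abs(f0))
    res = optimize.minimize(
        zfun, z0, jac=True, method="L-BFGS-B",
        options={
            "ftol": opts["tolerance"],
            "gtol": gtol,
            "maxiter": opts["max_iter"],
            "maxcor": 25,
        },
    )
    nit = int(res.nit)
    f, g = zfun(res.x)
    # the hard feasibility barrier can defeat the quasi-Newton line search
    # near the PD boundary; a trust-region Newton polish (Hessian-vector
    # products by differencing the analytic gradient) is immune to that
    for _ in range(2):
        if float(np.max(np.abs(g))) <= max(gtol, 1e-9 * (1.0 + abs(f))):
            break
        polish = optimize.minimize(
            zfun, res.x, jac=True, hessp=hessp, method="trust-ncg",
            options={"gtol": max(gtol * 1e-2, 1e-10), "maxiter": opts["max_iter"]},
        )
        if polish.fun > f + 1e-12 * (1.0 + abs(f)):
            break
        res = polish
        nit += int(polish.nit)
        f, g = zfun(res.x)
    res.nit = nit
    res.success = bool(res.success) or float(np.max(np.abs(g))) <= 1e-4 * (1.0 + abs(f))
    res.x = res.x * s
    return res


def fit(spec: TwoLevelModelSpec, stats: SufficientStatistics,
        options: dict | None = None) -> FitResult:
    """Fit a two-level model by quasi-Newton minimization of the ML
    discrepancy, from deterministic data-based starting values.

    The saturated mean structure is implicit (cluster summaries are centered
    at the grand mean); the reported ``minus2ll`` profiles the mean exactly.
    Non-convergence is flagged in the result, never silent.
    """
    options = dict(options or {})
    if stats.variable_names != spec.observed:
        stats = stats.subset(spec.observed)
    disc = _Discrepancy(stats)
    pm = _ParamMap(spec)

    # degenerate case: nothing free
    if pm.k == 0:
        sb, sw = _implied(spec, np.zeros(0))
        F = disc.value(sb, sw)
        if F is None:
            raise ValueError("fixed parameter values imply a non-PD covariance")
        return FitResult({}, disc.minus2ll(sb, sw), F, True, 0, 0.0, spec, stats,
                         sigma_w=sw, sigma_b=sb, mu_hat=disc.profiled_mu(sb, sw))

    start_override = options.pop("start", None)
    x0 = _default_start(pm, stats)
    if start_override:
        for lab, v in start_override.items():
            if lab in pm.labels:
                x0[pm.labels.index(lab)] = float(v)

    shared = _has_cross_level_labels(spec)
    if stats.balanced and spec.between.is_saturated and not shared:
        return _fit_profiled_between(spec, stats, disc, pm, x0, options)

    def objective(x):
        A, S = pm.matrices(x)
        try:
            sw, Bw, Sw = _level_sigma_and_cache(spec.within, A[WITHIN], S[WITHIN])
            sb, Bb, Sb = _level_sigma_and_cache(spec.between, A[BETWEEN], S[BETWEEN])
        except ValueError:
            return _BIG, np.zeros(pm.k)
        out = disc.value(sb, sw, weights=True)
        if out is None:
            return _BIG, np.zeros(pm.k)
        F, W_B, W_W, _ = out
        Tw, Xw = _level_grads(spec.within, Bw, Sw, W_W)
        Tb, Xb = _level_grads(spec.between, Bb, Sb, W_B)
        g = pm.gather_gradient({
            (WITHIN, "S"): Tw, (WITHIN, "A"): Xw,
            (BETWEEN, "S"): Tb, (BETWEEN, "A"): Xb,
        })
        return F, g

    f0 = objective(x0)[0]
    if f0 >= _BIG:
        # fall back to a heavily regularized start
        x0 = _default_start(pm, stats)
        for idx, slots in enumerate(pm.slots):
            lvl, mat, i, j = slots[0]
            if mat == "S" and i != j:
                x0[idx] *= 0.5
        if objective(x0)[0] >= _BIG:
            raise ValueError("could not find a feasible starting point")

    res = _minimize(objective, x0, options, scales=_param_scales(pm, stats))
    F, g = objective(res.x)
    gnorm = float(np.max(np.abs(g)))
    sb, sw = _implied(spec, res.x)
    converged = bool(res.success) and F < _BIG
    return FitResult(
        dict(zip(pm.labels, res.x)), disc.minus2ll(sb, sw), F, converged,
        int(res.nit), gnorm, spec, stats, sigma_w=sw, sigma_b=sb,
        mu_hat=disc.profiled_mu(sb, sw), message=str(res.message),
    )


def _has_cross_level_labels(spec: TwoLevelModelSpec) -> bool:
    w = {v for v in spec.within.labels.values()}
    b = {v for v in spec.between.labels.values()}
    return bool(w & b)


def _fit_profiled_between(spec, stats, disc, pm, x0, options) -> FitResult:
    """Balanced data with a saturated between level: the group covariance
    Sigma_g = Sigma_W + n Sigma_B is unrestricted, so it is profiled out at
    its observed analog and only the within level is optimized."""
    n = int(stats.n_j[0])
    S_bbar = stats.mean_S_B()
    cb = _chol_logdet_inv(S_bbar)
    if cb is None:
        raise ValueError(
            "average between matrix is singular (need more clusters than "
            "variables for a saturated between level)"
        )
    logdet_bbar = cb[0]
    p = stats.p
    nw = stats.N - stats.J
    const = stats.J * (logdet_bbar + p)
    S_pw = stats.pooled_within

    within_idx = [k for k, slots in enumerate(pm.slots) if slots[0][0] == WITHIN]
    lm = spec.within

    def w_objective(xw):
        x = np.zeros(pm.k)
        x[within_idx] = xw
        A, S = pm.matrices(x)
        try:
            sw, Bw, Sw = _level_sigma_and_cache(lm, A[WITHIN], S[WITHIN])
        except ValueError:
            return _BIG, np.zeros(len(within_idx))
        cw = _chol_logdet_inv(sw)
        if cw is None:
            return _BIG, np.zeros(len(within_idx))
        logdet_w, inv_w = cw
        F = const + nw * (logdet_w + float(np.sum(inv_w * S_pw)))
        W_W = nw * (inv_w - inv_w @ S_pw @ inv_w)
        Tw, Xw = _level_grads(lm, Bw, Sw, W_W)
        g_full = pm.gather_gradient({
            (WITHIN, "S"): Tw, (WITHIN, "A"): Xw,
            (BETWEEN, "S"): np.zeros((p, p)), (BETWEEN, "A"): np.zeros((p, p)),
        })
        return F, g_full[within_idx]

    if lm.is_saturated:
        # fully closed form: Sigma_W = pooled within
        xw = np.array([x0[k] for k in within_idx])
        order = [pm.slots[k][0] for k in within_idx]
        for t, (_, mat, i, j) in enumerate(order):
            xw[t] = S_pw[i, j]
        F = const + nw * (_chol_logdet_inv(S_pw)[0] + p)
        res_x, nit, gnorm, success, msg = xw, 0, 0.0, True, "closed form"
    else:
        scales = _param_scales(pm, stats)[within_idx]
        res = _minimize(w_objective, np.array([x0[k] for k in within_idx]),
                        options, scales=scales)
        res_x, nit, success, msg = res.x, int(res.nit), bool(res.success), str(res.message)
        F, g = w_objective(res.x)
        gnorm = float(np.max(np.abs(g)))

    x = np.zeros(pm.k)
    x[within_idx] = res_x
    A, S = pm.matrices(x)
    sw, _, _ = _level_sigma_and_cache(lm, A[WITHIN], S[WITHIN])
    sb = (S_bbar - sw) / n
    # write the profiled between estimates back into theta
    for k, slots in enumerate(pm.slots):
        lvl, mat, i, j = slots[0]
        if lvl == BETWEEN and mat == "S":
            x[k] = sb[i, j]
    return FitResult(
        dict(zip(pm.labels, x)), disc.minus2ll(sb, sw), F, success, nit, gnorm,
        spec, stats, sigma_w=sw, sigma_b=sb, mu_hat=disc.profiled_mu(sb, sw),
        message=msg,
    )


# ---------------------------------------------------------------------------
# Saturated two-level estimation (segregating step 1 backbone)
# ---------------------------------------------------------------------------

def _vech_indices(p: int):
    return [(i, j) for i in range(p) for j in range(i + 1)]


def fit_saturated(stats: SufficientStatistics,
                  options: dict | None = None) -> SaturatedEstimates:
    """ML estimates of (mu, Sigma_W, Sigma_B) with both levels unrestricted,
    plus asymptotic covariances of the vech'ed covariance estimates.

    Balanced data is solved in closed form (Sigma_W = pooled within;
    Sigma_B = between-means covariance minus Sigma_W / n); unbalanced data by
    quasi-Newton on (mu, vech Sigma_W, vech Sigma_B) starting from the
    balanced-form values.  Sigma_B may legitimately be indefinite; this is
    flagged, not rejected.
    """
    disc = _Discrepancy(stats)
    p = stats.p
    vech = _vech_indices(p)
    k = len(vech)

    if stats.balanced:
        n = int(stats.n_j[0])
        sigma_w = stats.pooled_within.copy()
        S_bbar = stats.mean_S_B()
        sigma_b = (S_bbar - sigma_w) / n
        mu = stats.grand_mean.copy()
        F = disc.value(sigma_b, sigma_w, mu=mu)
        if F is None:
            # degenerate between-group covariance (e.g. identical cluster
            # means): the estimates are still defined, the likelihood is not
            warn = ["between-group covariance is singular; likelihood unbounded"]
            _log.warning(warn[0])
            nan = float("nan") * np.ones((len(vech), len(vech)))
            return SaturatedEstimates(mu, sigma_w, sigma_b, nan, nan.copy(),
                                      float("-inf"), float("-inf"),
                                      sigma_b_psd=False, warnings=warn)
        minus2ll = F + stats.N * p * _LOG2PI
    else:
        res = _fit_saturated_unbalanced(stats, disc, options)
        mu, sigma_w, sigma_b, F = res
        minus2ll = disc.value(sigma_b, sigma_w, mu=mu) + stats.N * p * _LOG2PI

    acov_w, acov_b = _saturated_acov(disc, sigma_b, sigma_w, mu, vech)
    eigs = np.linalg.eigvalsh((sigma_b + sigma_b.T) / 2.0)
    psd = bool(eigs.min() > -1e-10 * max(1.0, eigs.max()))
    warn = [] if psd else ["between covariance estimate is not positive semi-definite"]
    if warn:
        _log.warning(warn[0])
    return SaturatedEstimates(mu, sigma_w, sigma_b, acov_w, acov_b,
                              minus2ll, F, sigma_b_psd=psd, warnings=warn)


def _fit_saturated_unbalanced(stats, disc, options):
    p = stats.p
    vech = _vech_indices(p)
    k = len(vech)
    nbar = stats.N / stats.J
    sw0 = stats.pooled_within
    sb0 = (stats.mean_S_B() - sw0) / nbar
    mu0 = stats.grand_mean

    def pack(mu, sw, sb):
        return np.concatenate([mu, [sw[i, j] for i, j in vech], [sb[i, j] for i, j in vech]])

    def unpack(x):
        mu = x[:p]
        sw = np.zeros((p, p))
        sb = np.zeros((p, p))
        for t, (i, j) in enumerate(vech):
            sw[i, j] = sw[j, i] = x[p + t]
            sb[i, j] = sb[j, i] = x[p + k + t]
        return mu, sw, sb

    def objective(x):
        mu, sw, sb = unpack(x)
        out = disc.value(sb, sw, mu=mu, weights=True)
        if out is None:
            return _BIG, np.zeros(len(x))
        F, W_B, W_W, g_mu = out
        g = np.zeros(len(x))
        g[:p] = g_mu
        for t, (i, j) in enumerate(vech):
            g[p + t] = W_W[i, i] if i == j else 2.0 * W_W[i, j]
            g[p + k + t] = W_B[i, i] if i == j else 2.0 * W_B[i, j]
        return F, g

    x0 = pack(mu0, sw0, sb0)
    if objective(x0)[0] >= _BIG:
        x0 = pack(mu0, sw0, _psd_clamp(sb0, 1e-4 * float(np.mean(np.diag(sw0))) / nbar))
    dw = np.maximum(np.abs(np.diag(sw0)), 1e-3 * float(np.abs(np.diag(sw0)).max()))
    db = np.maximum(np.abs(np.diag(sw0)) / nbar, 1e-3 * float(np.abs(np.diag(sw0)).max()) / nbar)
    scales = np.concatenate([
        np.sqrt(dw),
        [np.sqrt(dw[i] * dw[j]) for i, j in vech],
        [np.sqrt(db[i] * db[j]) for i, j in vech],
    ])
    res = _minimize(objective, x0, options, scales=scales)
    if not res.success:
        F, g = objective(res.x)
        if float(np.max(np.abs(g))) > 1e-3 * max(1.0, abs(F)):
            raise RuntimeError(
                f"saturated two-level fit did not reach gradient tolerance: {res.message}"
            )
    mu, sw, sb = unpack(res.x)
    return mu, sw, sb, objective(res.x)[0]


def _saturated_acov(disc, sigma_b, sigma_w, mu, vech):
    """Asymptotic covariances = inverse observed information of the vech
    blocks, via central differences of the analytic discrepancy gradient
    (the information for -l is half the discrepancy Hessian)."""
    k = len(vech)

    def grad(sw, sb):
        out = disc.value(sb, sw, mu=mu, weights=True)
        if out is None:
            raise ValueError("non-PD point while differentiating information")
        _, W_B, W_W, _ = out
        g = np.zeros(2 * k)
        for t, (i, j) in enumerate(vech):
            g[t] = W_W[i, i] if i == j else 2.0 * W_W[i, j]
            g[k + t] = W_B[i, i] if i == j else 2.0 * W_B[i, j]
        return g

    scale = max(float(np.mean(np.abs(np.diag(sigma_w)))), 1e-3)
    h = 1e-5 * scale
    H = np.zeros((2 * k, 2 * k))
    for t in range(2 * k):
        dsw = np.zeros_like(sigma_w)
        dsb = np.zeros_like(sigma_b)
        which, (i, j) = ("W", vech[t]) if t < k else ("B", vech[t - k])
        tgt = dsw if which == "W" else dsb
        tgt[i, j] = tgt[j, i] = h
        gp = grad(sigma_w + dsw, sigma_b + dsb)
        gm = grad(sigma_w - dsw, sigma_b - dsb)
        H[t] = (gp - gm) / (2.0 * h)
    H = (H + H.T) / 2.0
    # information of -l is H/2; acov = inverse
    try:
        acov = np.linalg.inv(H / 2.0)
    except np.linalg.LinAlgError:
        acov = np.linalg.pinv(H / 2.0)
    acov = (acov + acov.T) / 2.0
    return acov[:k, :k].copy(), acov[k:, k:].copy()


# ---------------------------------------------------------------------------
# Single-level fitting (segregating step 2 backbone)
# ---------------------------------------------------------------------------

def fit_single_level(model: LevelModel, S: np.ndarray, n_eff: int,
                     options: dict | None = None, approach: str = "single"):
    """Fit a single-level covariance structure model to an observed (or
    estimated) covariance matrix S.

    Minimizes log|Sigma(theta)| + tr(Sigma(theta)^{-1} S) - log|S| - p; the
    chi-square is (n_eff - 1) times the minimum.  Returns (FitResult,
    FitIndexReport) with standard single-level CFI (independence baseline,
    closed form) and RMSEA (multiplier n_eff - 1).
    """
    from .indices import build_single_level_report  # deferred: avoids cycle

    S = np.asarray(S, dtype=float)
    p = model.p
    if S.shape != (p, p):
        raise ValueError(f"S must be {p}x{p}")
    if n_eff < p + 1:
        raise ValueError("n_eff must exceed the number of variables")
    cs = _chol_logdet_inv(S)
    if cs is None:
        raise ValueError(
            "input covariance matrix is not positive definite; for a segregated "
            "between matrix this should be flagged and reported, not fitted"
        )
    logdet_s, _ = cs

    labels = model.free_params()
    slots = model.free_slots()
    label_of = [model.slot_label(s) for s in slots]
    index = {lab: labels.index(lab) for lab in labels}

    def build(theta):
        A = model.a_value.copy()
        Sm = model.s_value.copy()
        for slot, lab in zip(slots, label_of):
            v = theta[index[lab]]
            mat, i, j = slot
            if mat == "A":
                A[i, j] = v
            else:
                Sm[i, j] = Sm[j, i] = v
        return A, Sm

    def objective(theta):
        A, Sm = build(theta)
        try:
            sigma, B, Sm2 = _level_sigma_and_cache(model, A, Sm)
        except ValueError:
            return _BIG, np.zeros(len(labels))
        c = _chol_logdet_inv(sigma)
        if c is None:
            return _BIG, np.zeros(len(labels))
        logdet, inv = c
        F = logdet + float(np.sum(inv * S)) - logdet_s - p
        W = inv - inv @ S @ inv
        T, X = _level_grads(model, B, Sm2, W)
        g = np.zeros(len(labels))
        for slot, lab in zip(slots, label_of):
            mat, i, j = slot
            if mat == "A":
                g[index[lab]] += 2.0 * X[j, i]
            elif i == j:
                g[index[lab]] += T[i, i]
            else:
                g[index[lab]] += 2.0 * T[i, j]
        return F, g

    if model.is_saturated:
        theta = np.zeros(len(labels))
        for slot, lab in zip(slots, label_of):
            _, i, j = slot
            theta[index[lab]] = S[i, j]
        F, nit, gnorm, success, msg = 0.0, 0, 0.0, True, "closed form"
    else:
        x0 = _single_level_start(model, S, labels, slots, label_of, index)
        if objective(x0)[0] >= _BIG:
            x0 = 0.5 * x0
        obs_pos = {v: k for k, v in enumerate(model.observed)}
        d = np.abs(np.diag(S))
        d = np.maximum(d, 1e-3 * float(d.max()))
        scales = np.ones(len(labels))
        for slot, lab in zip(slots, label_of):
            mat, i, j = slot
            ni, nj = model.names[i], model.names[j]
            di = d[obs_pos[ni]] if ni in obs_pos else 1.0
            dj = d[obs_pos[nj]] if nj in obs_pos else 1.0
            scales[index[lab]] = np.sqrt(di / dj) if mat == "A" else np.sqrt(di * dj)
        res = _minimize(objective, x0, options, scales=scales)
        theta, nit, success, msg = res.x, int(res.nit), bool(res.success), str(res.message)
        F, g = objective(theta)
        gnorm = float(np.max(np.abs(g)))

    A, Sm = build(theta)
    sigma, _, _ = _level_sigma_and_cache(model, A, Sm)
    chi2 = max((n_eff - 1) * F, 0.0)
    df = p * (p + 1) // 2 - len(labels)
    fr = FitResult(dict(zip(labels, theta)), float("nan"), F, success, nit, gnorm,
                   None, None, sigma_w=sigma, message=msg)
    report = build_single_level_report(chi2, df, S, n_eff, approach=approach,
                                       converged=success)
    return fr, report


def _single_level_start(model, S, labels, slots, label_of, index):
    x0 = np.zeros(len(labels))
    obs_pos = {v: k for k, v in enumerate(model.observed)}
    for slot, lab in zip(slots, label_of):
        mat, i, j = slot
        ni, nj = model.names[i], model.names[j]
        if mat == "S" and i == j:
            x0[index[lab]] = S[obs_pos[ni], obs_pos[ni]] if ni in obs_pos else 1.0
        elif mat == "A" and nj not in obs_pos:
            x0[index[lab]] = 0.7
    # OLS starts for observed-variable regressions
    for i in range(model.m):
        preds = [j for j in range(model.m) if model.a_free[i, j]]
        ni = model.names[i]
        if not preds or ni not in obs_pos:
            continue
        if any(model.names[j] not in obs_pos for j in preds):
            continue
        pi = obs_pos[ni]
        pj = [obs_pos[model.names[j]] for j in preds]
        try:
            b = np.linalg.solve(S[np.ix_(pj, pj)], S[pj, pi])
        except np.linalg.LinAlgError:
            continue
        for j, bj in zip(preds, b):
            x0[index[model.slot_label(("A", i, j))]] = float(bj)
        rv = float(S[pi, pi] - b @ S[pj, pi])
        x0[index[model.slot_label(("S", i, i))]] = max(rv, 0.05 * float(S[pi, pi]))
    return x0
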