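"""Two-level structural model specification.

Each level (within-cluster and between-cluster) is a path/factor model in the
reticular (RAM) parameterization: directed paths collected in ``A``, symmetric
(co)variances in ``S``, and the level's implied covariance of the observed
variables is

    Sigma = F (I - A)^{-1} S (I - A)^{-T} F'

with ``F`` the observed-variable selection matrix.  Entries of A and S are
either fixed to a value or free; free entries carry labels, and a label shared
between the two levels imposes a cross-level equality constraint.

Models are written in a lavaan-style equation syntax under ``within:`` and
``between:`` blocks::

    within: |
      MConf ~ Female
      MInt  ~ Female
      MAch  ~ MConf + MUtil + MInt + Female
      MConf ~~ MUtil
    between: saturated

Defaults: every variable's (residual) variance is free; covariances are zero
unless listed; a directed path exists only if listed.  ``fix(v)*x`` (or a bare
number) fixes an entry, any other prefix ``label*x`` names it.  ``f =~ i1 +
i2 + i3`` defines a latent factor with the first loading fixed to 1 unless it
carries an explicit modifier.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "LevelModel",
    "TwoLevelModelSpec",
    "implied_covariance",
    "saturate",
    "independence",
    "count_df",
    "parse_model",
    "read_model",
]

WITHIN = "within"
BETWEEN = "between"


# ---------------------------------------------------------------------------
# Level model
# ---------------------------------------------------------------------------

@dataclass
class LevelModel:
    """One level's structural model in RAM form.

    ``a_free``/``s_free`` mark free entries; ``a_value``/``s_value`` hold the
    fixed values (and are ignored where free).  ``labels`` maps ("A"|"S", i, j)
    of a free entry to a user label, if one was given.
    """

    names: list[str]
    observed: list[str]
    a_free: np.ndarray
    a_value: np.ndarray
    s_free: np.ndarray
    s_value: np.ndarray
    labels: dict = field(default_factory=dict)

    @classmethod
    def empty(cls, observed: list[str], latents: list[str] | None = None) -> "LevelModel":
        names = list(observed) + list(latents or [])
        m = len(names)
        lm = cls(
            names=names,
            observed=list(observed),
            a_free=np.zeros((m, m), dtype=bool),
            a_value=np.zeros((m, m)),
            s_free=np.zeros((m, m), dtype=bool),
            s_value=np.zeros((m, m)),
        )
        lm.s_free[np.diag_indices(m)] = True  # variances free by default
        return lm

    @classmethod
    def saturated(cls, observed: list[str]) -> "LevelModel":
        lm = cls.empty(observed)
        lm.s_free[:, :] = True
        return lm

    @classmethod
    def independence(cls, observed: list[str]) -> "LevelModel":
        return cls.empty(observed)

    # -- structure queries --------------------------------------------------
    @property
    def m(self) -> int:
        return len(self.names)

    @property
    def p(self) -> int:
        return len(self.observed)

    @property
    def observed_idx(self) -> np.ndarray:
        return np.asarray([self.names.index(v) for v in self.observed])

    @property
    def is_saturated(self) -> bool:
        return (
            self.m == self.p
            and not self.a_free.any()
            and not self.a_value.any()
            and self.s_free.all()
        )

    def validate(self) -> None:
        if self.a_free.any(axis=None) or self.a_value.any():
            if np.any(np.diag(self.a_free)) or np.any(np.diag(self.a_value)):
                raise ValueError("path matrix has nonzero diagonal entries")
        adj = self.a_free | (self.a_value != 0)
        # recursive (acyclic) check: A[i, j] != 0 means path j -> i
        order = np.arange(self.m)
        reach = adj.copy()
        for _ in range(self.m):
            reach = reach | (reach @ adj)
        if np.any(np.diag(reach)):
            raise ValueError("non-recursive model: the path diagram contains a cycle")
        del order
        if not np.array_equal(self.s_free, self.s_free.T):
            raise ValueError("S pattern must be symmetric")
        if not np.allclose(self.s_value, self.s_value.T):
            raise ValueError("fixed S values must be symmetric")

    # -- free parameters ----------------------------------------------------
    def free_slots(self) -> list[tuple[str, int, int]]:
        """Free entries in canonical order: A row-major, then S lower triangle."""
        slots = [("A", i, j) for i in range(self.m) for j in range(self.m) if self.a_free[i, j]]
        slots += [("S", i, j) for i in range(self.m) for j in range(i + 1) if self.s_free[i, j]]
        return slots

    def free_params(self) -> list[str]:
        """Distinct parameter labels at this level, in canonical slot order."""
        seen, out = set(), []
        for slot in self.free_slots():
            lab = self.labels.get(slot) or self._auto_label(slot)
            if lab not in seen:
                seen.add(lab)
                out.append(lab)
        return out

    def _auto_label(self, slot) -> str:
        mat, i, j = slot
        if mat == "A":
            return f"{self.names[i]}~{self.names[j]}"
        a, b = sorted((self.names[i], self.names[j]))
        return f"{a}~~{b}"

    def slot_label(self, slot) -> str:
        return self.labels.get(slot) or self._auto_label(slot)

    @property
    def n_free(self) -> int:
        return len(self.free_params())

    def build_matrices(self, theta) -> tuple[np.ndarray, np.ndarray]:
        """Fill (A, S) from a per-level parameter vector in free_params order."""
        order = self.free_params()
        if len(theta) != len(order):
            raise ValueError(f"expected {len(order)} parameters, got {len(theta)}")
        value = dict(zip(order, np.asarray(theta, dtype=float)))
        A = self.a_value.copy()
        S = self.s_value.copy()
        for slot in self.free_slots():
            v = value[self.slot_label(slot)]
            mat, i, j = slot
            if mat == "A":
                A[i, j] = v
            else:
                S[i, j] = v
                S[j, i] = v
        return A, S

    def implied_cov_from(self, A: np.ndarray, S: np.ndarray) -> np.ndarray:
        I = np.eye(self.m)
        try:
            B = np.linalg.solve(I - A, I)
        except np.linalg.LinAlgError as err:
            raise ValueError("non-recursive or ill-specified path matrix") from err
        full = B @ S @ B.T
        idx = self.observed_idx
        sigma = full[np.ix_(idx, idx)]
        return (sigma + sigma.T) / 2.0


def implied_covariance(model: LevelModel, theta_level) -> np.ndarray:
    """Observed-variable covariance implied by one level at ``theta_level``.

    ``theta_level`` follows ``model.free_params()`` order.
    """
    A, S = model.build_matrices(theta_level)
    return model.implied_cov_from(A, S)


# ---------------------------------------------------------------------------
# Two-level specification
# ---------------------------------------------------------------------------

@dataclass
class TwoLevelModelSpec:
    within: LevelModel
    between: LevelModel
    mean_structure: str = "saturated"
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.within.observed != self.between.observed:
            raise ValueError(
                "within and between levels must share the same observed "
                f"variables in the same order (got {self.within.observed} vs "
                f"{self.between.observed})"
            )
        self.within.validate()
        self.between.validate()

    @property
    def observed(self) -> list[str]:
        return self.within.observed

    @property
    def p(self) -> int:
        return len(self.observed)

    def level(self, which: str) -> LevelModel:
        if which == WITHIN:
            return self.within
        if which == BETWEEN:
            return self.between
        raise ValueError(f"level must be '{WITHIN}' or '{BETWEEN}', got {which!r}")


def saturate(spec: TwoLevelModelSpec, level: str) -> TwoLevelModelSpec:
    """Copy of ``spec`` with the indicated level replaced by an unrestricted
    covariance model (p(p+1)/2 free parameters); the other level untouched."""
    sat = LevelModel.saturated(spec.observed)
    if level == WITHIN:
        return replace(spec, within=sat)
    if level == BETWEEN:
        return replace(spec, between=sat)
    raise ValueError(f"level must be '{WITHIN}' or '{BETWEEN}', got {level!r}")


def independence(spec: TwoLevelModelSpec, level: str) -> TwoLevelModelSpec:
    """Copy of ``spec`` with the indicated level diagonal-only (free variances,
    zero covariances); the other level untouched."""
    ind = LevelModel.independence(spec.observed)
    if level == WITHIN:
        return replace(spec, within=ind)
    if level == BETWEEN:
        return replace(spec, between=ind)
    raise ValueError(f"level must be '{WITHIN}' or '{BETWEEN}', got {level!r}")


def spec_param_labels(spec: TwoLevelModelSpec) -> tuple[list[str], list[str]]:
    """Distinct parameter labels per level after cross-level deduplication.

    Auto-generated labels are level-prefixed (never shared); user labels are
    shared verbatim, so a label appearing at both levels is a single parameter
    and is attributed to the within level for df bookkeeping.
    """
    def level_labels(lm: LevelModel, prefix: str) -> list[str]:
        seen, out = set(), []
        for slot in lm.free_slots():
            user = lm.labels.get(slot)
            lab = user if user is not None else f"{prefix}:{lm._auto_label(slot)}"
            if lab not in seen:
                seen.add(lab)
                out.append(lab)
        return out

    w = level_labels(spec.within, "w")
    b = level_labels(spec.between, "b")
    b = [lab for lab in b if lab not in set(w)]
    return w, b


def count_df(spec: TwoLevelModelSpec, p: int | None = None) -> tuple[int, int, int]:
    """Degrees of freedom (total, between, within).

    Each level offers p(p+1)/2 covariance moments; df is moments minus that
    level's free-parameter count (cross-level shared labels counted once, at
    the within level).  The saturated mean structure contributes zero.
    """
    if p is None:
        p = spec.p
    moments = p * (p + 1) // 2
    w_labels, b_labels = spec_param_labels(spec)
    df_w = moments - len(w_labels)
    df_b = moments - len(b_labels)
    if df_w < 0 or df_b < 0:
        raise ValueError(
            f"under-identified level: df_within={df_w}, df_between={df_b}"
        )
    return df_w + df_b, df_b, df_w


# ---------------------------------------------------------------------------
# Equation-syntax parser
# ---------------------------------------------------------------------------

_TERM_RE = re.compile(r"^(?:(.+)\*)?([A-Za-z_][\w.]*)$")
_FIX_RE = re.compile(r"^fix\(\s*([-+0-9.eE]+)\s*\)$")


def _parse_term(term: str):
    """Return (kind, payload, var): kind in {'free', 'fixed', 'label'}."""
    term = term.strip()
    m = _TERM_RE.match(term)
    if not m:
        raise ValueError(f"cannot parse term {term!r}")
    mod, var = m.group(1), m.group(2)
    if mod is None:
        return "free", None, var
    mod = mod.strip()
    fx = _FIX_RE.match(mod)
    if fx:
        return "fixed", float(fx.group(1)), var
    try:
        return "fixed", float(mod), var
    except ValueError:
        return "label", mod, var


def _split_equations(block) -> list[str]:
    if isinstance(block, str):
        lines = re.split(r"[\n;]", block)
    else:
        lines = []
        for item in block:
            lines.extend(re.split(r"[\n;]", str(item)))
    out = []
    for ln in lines:
        ln = ln.split("#", 1)[0].strip()
        if ln:
            out.append(ln)
    return out


def _collect_vars(equations: list[str]) -> tuple[list[str], list[str]]:
    """Ordered (all-mentioned, latent) variable names from equation lines."""
    order: list[str] = []
    latents: list[str] = []

    def note(v):
        if v not in order:
            order.append(v)

    for eq in equations:
        for op in ("=~", "~~", "~"):
            if op in eq:
                lhs, rhs = eq.split(op, 1)
                lhs = lhs.strip()
                note(lhs)
                if op == "=~" and lhs not in latents:
                    latents.append(lhs)
                for term in rhs.split("+"):
                    note(_parse_term(term)[2])
                break
        else:
            raise ValueError(f"equation {eq!r} has no operator (~, ~~ or =~)")
    return order, latents


def _build_level(equations: list[str], observed: list[str]) -> LevelModel:
    _, latents = _collect_vars(equations)
    lm = LevelModel.empty(observed, latents)
    idx = {v: k for k, v in enumerate(lm.names)}

    def set_a(i, j, kind, payload):
        if kind == "fixed":
            lm.a_free[i, j] = False
            lm.a_value[i, j] = payload
        else:
            lm.a_free[i, j] = True
            if kind == "label":
                lm.labels[("A", i, j)] = payload

    def set_s(i, j, kind, payload):
        if kind == "fixed":
            lm.s_free[i, j] = lm.s_free[j, i] = False
            lm.s_value[i, j] = lm.s_value[j, i] = payload
        else:
            lm.s_free[i, j] = lm.s_free[j, i] = True
            if kind == "label":
                key = ("S", max(i, j), min(i, j))
                lm.labels[key] = payload

    for eq in equations:
        if "=~" in eq:
            lhs, rhs = (s.strip() for s in eq.split("=~", 1))
            terms = [t for t in rhs.split("+")]
            for k, term in enumerate(terms):
                kind, payload, var = _parse_term(term)
                if k == 0 and kind == "free":
                    kind, payload = "fixed", 1.0  # anchor the factor scale
                set_a(idx[var], idx[lhs], kind, payload)
        elif "~~" in eq:
            lhs, rhs = (s.strip() for s in eq.split("~~", 1))
            for term in rhs.split("+"):
                kind, payload, var = _parse_term(term)
                i, j = idx[lhs], idx[var]
                set_s(max(i, j), min(i, j), kind, payload)
        elif "~" in eq:
            lhs, rhs = (s.strip() for s in eq.split("~", 1))
            for term in rhs.split("+"):
                kind, payload, var = _parse_term(term)
                set_a(idx[lhs], idx[var], kind, payload)
    # canonicalize label keys that were stored as ("S", i, j) with i >= j
    lm.labels = {
        (mat, i, j) if mat == "A" or i >= j else (mat, j, i): v
        for (mat, i, j), v in lm.labels.items()
    }
    return lm


def parse_model(source: str | dict) -> TwoLevelModelSpec:
    """Parse a model configuration (YAML text or an already-loaded mapping).

    Keys: ``within`` and ``between`` (equation block, or the strings
    ``saturated`` / ``independence``), optional ``variables`` fixing the
    observed order, optional ``options`` mapping passed through to fitting.
    """
    cfg = yaml.safe_load(source) if isinstance(source, str) else dict(source)
    if not isinstance(cfg, dict):
        raise ValueError("model configuration must be a mapping")
    blocks = {}
    for key in (WITHIN, BETWEEN):
        if key not in cfg:
            raise ValueError(f"model configuration is missing the '{key}:' block")
        blocks[key] = cfg[key]

    # determine observed variables
    eq_lines = {
        key: _split_equations(val) if not _is_keyword(val) else []
        for key, val in blocks.items()
    }
    if "variables" in cfg:
        observed = [str(v) for v in cfg["variables"]]
    else:
        observed = []
        for key in (WITHIN, BETWEEN):
            mentioned, latents = _collect_vars(eq_lines[key])
            for v in mentioned:
                if v not in latents and v not in observed:
                    observed.append(v)
        if not observed:
            raise ValueError(
                "cannot infer observed variables: give a 'variables:' list when "
                "both levels are saturated/independence keywords"
            )

    levels = {}
    for key in (WITHIN, BETWEEN):
        val = blocks[key]
        if _is_keyword(val):
            kw = str(val).strip().lower()
            levels[key] = (
                LevelModel.saturated(observed) if kw == "saturated"
                else LevelModel.independence(observed)
            )
        else:
            levels[key] = _build_level(eq_lines[key], observed)

    return TwoLevelModelSpec(
        within=levels[WITHIN],
        between=levels[BETWEEN],
        options=dict(cfg.get("options") or {}),
    )


def _is_keyword(val) -> bool:
    return isinstance(val, str) and val.strip().lower() in ("saturated", "independence")


def read_model(path) -> TwoLevelModelSpec:
    """Load a model configuration file."""
    with open(path) as fh:
        return parse_model(fh.read())
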