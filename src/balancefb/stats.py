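"""Weighted group statistics for cohort outcome tables.

Outcomes (bin averages, CCI, gains, cost improvements) are compared
between groups with a linear mixed model: fixed effects of group and an
ordinal condition (time bin 1-3 or perturbation level 1-4, coded
numerically), a random intercept per participant nested within group,
and per-observation weights equal to the inverse of the outcome
variance across all observations within the same group x condition
cell.  Multiple testing within a family uses the Bonferroni-Holm
step-down procedure; raw and corrected decisions are both reported.

The random-intercept model is fit by profiled REML: for a variance
ratio lambda = tau^2/sigma^2 the per-subject covariance blocks are
diag(1/w) + lambda * 11', inverted in closed form (Woodbury), and
lambda is optimised by bounded scalar search.  Wald t-tests use
containment degrees of freedom (between-subject effects: n_subjects -
2; within-subject effects: n_obs - n_subjects - #within coefficients).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

VARIANCE_FLOOR = 1e-8


class WeightingError(ValueError):
    pass


class SchemaError(ValueError):
    pass


class UsageError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# weights

def compute_weights(
    table: pd.DataFrame,
    value_col: str = "value",
    cell_cols: Sequence[str] = ("group", "condition"),
    weight_col: str = "weight",
) -> pd.DataFrame:
    """Attach inverse-variance weights per group x condition cell.

    w_i = 1 / var(y within the observation's cell), sample variance with
    ddof=1.  Cells need >= 2 observations; degenerate (constant) cells
    get a floored variance with a warning.  Row order is preserved.
    """
    df = table.copy()
    for col in cell_cols:
        if col not in df.columns:
            raise SchemaError(f"missing cell column {col!r}")
    weights = np.empty(len(df))
    for key, idx in df.groupby(list(cell_cols), sort=False).groups.items():
        vals = df.loc[idx, value_col].to_numpy(dtype=float)
        if vals.size < 2:
            raise WeightingError(
                f"cell {key} has {vals.size} observation(s); need >= 2"
            )
        var = float(np.var(vals, ddof=1))
        if var < VARIANCE_FLOOR:
            warnings.warn(f"cell {key}: variance {var:.3g} floored at {VARIANCE_FLOOR}")
            var = VARIANCE_FLOOR
        weights[df.index.get_indexer(idx)] = 1.0 / var
    df[weight_col] = weights
    return df


# ---------------------------------------------------------------------------
# weighted random-intercept mixed model

@dataclass
class ModelResult:
    params: "pd.Series"
    se: "pd.Series"
    ci_low: "pd.Series"
    ci_high: "pd.Series"
    pvalues: "pd.Series"
    dof: "pd.Series"
    lambda_ratio: float
    sigma2: float
    n_obs: int
    n_subjects: int
    effect_tested: str
    holm_significant: Optional[bool] = None

    @property
    def p_effect(self) -> float:
        return float(self.pvalues[self.effect_tested])


class _Profile:
    """Profiled-REML machinery over subject blocks."""

    def __init__(self, y, X, subjects, weights):
        self.blocks = []
        order = pd.unique(subjects)
        for s in order:
            m = subjects == s
            self.blocks.append((y[m], X[m], weights[m]))
        self.n, self.p = X.shape
        self.n_subjects = len(order)

    def _assemble(self, lam: float):
        p = self.p
        A = np.zeros((p, p))
        b = np.zeros(p)
        q = 0.0
        ld = 0.0
        for y_i, X_i, w_i in self.blocks:
            Dinv = w_i  # inverse of diag(1/w)
            s = 1.0 + lam * Dinv.sum()
            # Woodbury: Vinv = D^-1 - lam (D^-1 1)(1' D^-1) / s
            u = Dinv  # D^-1 @ 1
            XtD = X_i * Dinv[:, None]
            Xu = X_i.T @ u
            yu = float(y_i @ u)
            A += X_i.T @ XtD - (lam / s) * np.outer(Xu, Xu)
            b += X_i.T @ (Dinv * y_i) - (lam / s) * Xu * yu
            q += float(y_i @ (Dinv * y_i)) - (lam / s) * yu * yu
            ld += float(np.sum(np.log(1.0 / w_i))) + np.log(s)
        return A, b, q, ld

    def reml(self, lam: float) -> float:
        A, b, q, ld = self._assemble(lam)
        try:
            beta = np.linalg.solve(A, b)
            _, logdet_A = np.linalg.slogdet(A)
        except np.linalg.LinAlgError:
            return np.inf
        rss = max(q - beta @ b, 1e-300)
        dfree = self.n - self.p
        sigma2 = rss / dfree
        return dfree * np.log(sigma2) + ld + logdet_A

    def fit(self):
        res = optimize.minimize_scalar(
            lambda u: self.reml(np.exp(u)), bounds=(-12.0, 8.0),
            method="bounded", options={"xatol": 1e-6},
        )
        lam = float(np.exp(res.x))
        # allow the boundary lambda -> 0
        if self.reml(0.0) <= self.reml(lam):
            lam = 0.0
        A, b, q, _ = self._assemble(lam)
        try:
            Ainv = np.linalg.inv(A)
        except np.linalg.LinAlgError as exc:
            raise UsageError(
                f"singular fixed-effects design (n={self.n}, p={self.p}); "
                "check for collinear columns"
            ) from exc
        beta = Ainv @ b
        sigma2 = max(q - beta @ b, 1e-300) / (self.n - self.p)
        cov = sigma2 * Ainv
        return beta, cov, lam, sigma2


def _condition_codes(cond: pd.Series) -> np.ndarray:
    """Ordinal condition -> numeric codes 1..k (already-numeric values
    pass through)."""
    if pd.api.types.is_numeric_dtype(cond):
        return cond.to_numpy(dtype=float)
    levels = sorted(cond.unique())
    mapping = {c: i + 1.0 for i, c in enumerate(levels)}
    return cond.map(mapping).to_numpy(dtype=float)


def fit_group_model(
    table: pd.DataFrame,
    value_col: str = "value",
    weight_col: str = "weight",
    effect: str = "group",
    condition_col: str = "condition",
    alpha: float = 0.05,
) -> ModelResult:
    """Weighted mixed model y ~ group * condition + (1 | subject).

    ``effect`` selects the hypothesis of interest: ``"group"`` (main
    effect, model without interaction) or ``"interaction"`` (group x
    condition).  Group coding: sorted labels, second = 1.
    """
    for col in ("subject_id", "group", condition_col, value_col, weight_col):
        if col not in table.columns:
            raise SchemaError(f"missing column {col!r}")
    if effect not in ("group", "interaction"):
        raise UsageError(f"unknown effect {effect!r}")
    df = table.reset_index(drop=True)
    y = df[value_col].to_numpy(dtype=float)
    w = df[weight_col].to_numpy(dtype=float)
    if np.any(w <= 0):
        raise WeightingError("weights must be strictly positive")
    glabels = sorted(df["group"].unique())
    if len(glabels) != 2:
        raise SchemaError(f"need exactly 2 groups, got {glabels}")
    g = (df["group"] == glabels[1]).to_numpy(dtype=float)
    c = _condition_codes(df[condition_col])
    c = c - c.mean()  # center so the group effect is at the mean condition
    names = ["intercept", "group", "condition"]
    cols = [np.ones(len(df)), g, c]
    if effect == "interaction":
        names.append("interaction")
        cols.append(g * c)
    X = np.stack(cols, axis=1)
    subjects = df["subject_id"].to_numpy()
    prof = _Profile(y, X, subjects, w)
    beta, cov, lam, sigma2 = prof.fit()
    se = np.sqrt(np.diag(cov))
    n_sub = prof.n_subjects
    n_within = len(names) - 2  # condition (+ interaction)
    dof = []
    for name in names:
        if name in ("intercept", "group"):
            dof.append(max(n_sub - 2, 1))
        else:
            dof.append(max(len(df) - n_sub - n_within, 1))
    dof = np.asarray(dof, dtype=float)
    tvals = beta / se
    pvals = 2.0 * sps.t.sf(np.abs(tvals), dof)
    tcrit = sps.t.ppf(1 - alpha / 2, dof)
    idx = pd.Index(names)
    return ModelResult(
        params=pd.Series(beta, index=idx),
        se=pd.Series(se, index=idx),
        ci_low=pd.Series(beta - tcrit * se, index=idx),
        ci_high=pd.Series(beta + tcrit * se, index=idx),
        pvalues=pd.Series(pvals, index=idx),
        dof=pd.Series(dof, index=idx),
        lambda_ratio=lam,
        sigma2=sigma2,
        n_obs=len(df),
        n_subjects=n_sub,
        effect_tested=effect,
    )


# ---------------------------------------------------------------------------
# Bonferroni-Holm

@dataclass
class HolmResult:
    reject: np.ndarray          # decision per hypothesis, input order
    alpha_steps: np.ndarray     # threshold each p was compared against
    alpha: float

    def __iter__(self):
        return iter(self.reject)


def holm_correct(pvals: Sequence[float], alpha: float = 0.05) -> HolmResult:
    """Step-down Holm procedure.

    Sort p ascending; compare p_(k) to alpha/(m - k + 1); reject until
    the first failure, then fail everything after.  Returns decisions in
    the input order along with the stepwise alpha levels.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a non-empty 1-d sequence")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    steps = np.empty(m)
    failed = False
    for k, i in enumerate(order):
        threshold = alpha / (m - k)
        steps[i] = threshold
        if not failed and p[i] < threshold:
            reject[i] = True
        else:
            failed = True
    return HolmResult(reject=reject, alpha_steps=steps, alpha=alpha)


# ---------------------------------------------------------------------------
# post-hoc contrasts

@dataclass
class Contrast:
    name: str
    estimate: float
    se: float
    dof: float
    pvalue: float
    holm_alpha: float = np.nan
    significant: bool = False


def _weighted_group_contrast(sub: pd.DataFrame, value_col: str, weight_col: str
                             ) -> Tuple[float, float, float, float]:
    """Weighted two-sample comparison (one observation per subject)."""
    glabels = sorted(sub["group"].unique())
    est_se = []
    for gl in glabels:
        rows = sub[sub["group"] == gl]
        w = rows[weight_col].to_numpy(dtype=float)
        v = rows[value_col].to_numpy(dtype=float)
        mean = float(np.sum(w * v) / np.sum(w))
        # weighted variance of the mean with a small-sample correction
        n = len(v)
        resid = v - mean
        var_mean = float(np.sum(w * resid**2) / np.sum(w)) / max(n - 1, 1)
        est_se.append((mean, var_mean, n))
    diff = est_se[1][0] - est_se[0][0]
    se = float(np.sqrt(est_se[0][1] + est_se[1][1]))
    dof = float(est_se[0][2] + est_se[1][2] - 2)
    t = diff / se if se > 0 else 0.0
    p = 2.0 * sps.t.sf(abs(t), dof)
    return diff, se, dof, float(p)


def posthoc_interaction(
    table: pd.DataFrame,
    model: ModelResult,
    value_col: str = "value",
    weight_col: str = "weight",
    condition_col: str = "condition",
    alpha: float = 0.05,
) -> List[Contrast]:
    """Post-hoc family after a significant group x condition interaction.

    Two kinds of contrasts, Holm-corrected together: the group contrast
    within each condition, and the between-group difference in the
    condition-to-condition change (paired per subject).  Raises if the
    fitted model's interaction is not significant at ``alpha``.
    """
    if model.effect_tested != "interaction":
        raise UsageError("post-hoc requires a model fitted with effect='interaction'")
    if not model.p_effect < alpha:
        raise UsageError(
            f"interaction p={model.p_effect:.3g} not significant at {alpha}"
        )
    df = table.reset_index(drop=True)
    conditions = sorted(df[condition_col].unique())
    glabels = sorted(df["group"].unique())
    contrasts: List[Contrast] = []
    for cond in conditions:
        sub = df[df[condition_col] == cond]
        est, se, dof, p = _weighted_group_contrast(sub, value_col, weight_col)
        contrasts.append(Contrast(
            name=f"{glabels[1]}-{glabels[0]} @ {cond}",
            estimate=est, se=se, dof=dof, pvalue=p,
        ))
    wide = df.pivot_table(index=["subject_id", "group"],
                          columns=condition_col, values=value_col)
    for c0, c1 in zip(conditions[:-1], conditions[1:]):
        delta = (wide[c1] - wide[c0]).dropna().reset_index()
        vals = {gl: delta.loc[delta["group"] == gl, 0].to_numpy(dtype=float)
                for gl in glabels}
        a, b = vals[glabels[0]], vals[glabels[1]]
        est = float(b.mean() - a.mean())
        se = float(np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size))
        dof = float(a.size + b.size - 2)
        t = est / se if se > 0 else 0.0
        p = 2.0 * sps.t.sf(abs(t), dof)
        contrasts.append(Contrast(
            name=f"change {c0}->{c1}: {glabels[1]} vs {glabels[0]}",
            estimate=est, se=se, dof=dof, pvalue=float(p),
        ))
    holm = holm_correct([c.pvalue for c in contrasts], alpha)
    for c, rej, a_step in zip(contrasts, holm.reject, holm.alpha_steps):
        c.significant = bool(rej)
        c.holm_alpha = float(a_step)
    return contrasts


def results_table(results: Dict[str, ModelResult], alpha: float = 0.05
                  ) -> pd.DataFrame:
    """Family-wise summary: raw p, Holm step alpha and both decisions,
    one row per outcome in the family."""
    names = list(results)
    pvals = [results[n].p_effect for n in names]
    holm = holm_correct(pvals, alpha)
    rows = []
    for n, p, rej, a_step in zip(names, pvals, holm.reject, holm.alpha_steps):
        r = results[n]
        rows.append(dict(
            outcome=n,
            effect=r.effect_tested,
            estimate=float(r.params[r.effect_tested]),
            ci_low=float(r.ci_low[r.effect_tested]),
            ci_high=float(r.ci_high[r.effect_tested]),
            p_raw=p,
            significant_raw=bool(p < alpha),
            holm_alpha=float(a_step),
            significant_holm=bool(rej),
        ))
    return pd.DataFrame(rows)
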