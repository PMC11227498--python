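"""Kaplan-Meier estimation, weighted log-rank tests, and Cox
proportional-hazards fitting.

The k-sample test engine computes the classic observed-minus-expected
sums with hypergeometric variances at each distinct event time; the
Gehan-Breslow (Wilcoxon) variant weights each time by the total number
at risk.  Cox models maximize the partial likelihood by Newton-Raphson
with Efron (default) or Breslow tie handling.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm

from .cohort import Cohort, Marker, Pattern, Stage
from .errors import FieldRangeError


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit estimate.

    ``times`` are the distinct event times in ascending order;
    ``survival[i]`` is S(t) just after ``times[i]``; ``at_risk[i]`` and
    ``events[i]`` are the risk-set size and death count at ``times[i]``.
    ``censor_times`` marks censored observation times.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    censor_times: np.ndarray

    def __post_init__(self) -> None:
        s = self.survival
        if s.size:
            if s.max() > 1 + 1e-12 or s.min() < -1e-12:
                raise FieldRangeError("survival outside [0, 1]")
            if np.any(np.diff(s) > 1e-12):
                raise FieldRangeError("survival must be non-increasing")
            if np.any(np.diff(self.at_risk) >= 0):
                raise FieldRangeError("at-risk counts must strictly decrease")

    def at(self, t: float) -> float:
        """S(t): survival just after time t."""
        idx = np.searchsorted(self.times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


def _validate_te(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.ndim != 1 or t.shape != e.shape or t.size == 0:
        raise FieldRangeError("times and events must be equal-length, non-empty")
    if (t < 0).any():
        raise FieldRangeError("negative survival time")
    return t, e


def km_estimate(times, events) -> SurvivalCurve:
    """Product-limit estimator; censored-only data yields S(t) = 1."""
    t, e = _validate_te(times, events)
    event_times = np.unique(t[e])
    at_risk = np.array([(t >= u).sum() for u in event_times], dtype=int)
    deaths = np.array([((t == u) & e).sum() for u in event_times], dtype=int)
    with np.errstate(divide="ignore", invalid="ignore"):
        surv = np.cumprod(1.0 - deaths / at_risk) if event_times.size else np.array([])
    return SurvivalCurve(
        times=event_times,
        survival=np.asarray(surv, dtype=float),
        at_risk=at_risk,
        events=deaths,
        censor_times=np.sort(t[~e]),
    )


# ---------------------------------------------------------------------------
# Weighted log-rank family
# ---------------------------------------------------------------------------

def _weighted_logrank(groups, weight: str) -> tuple[float, int, float]:
    k = len(groups)
    if k < 2:
        raise FieldRangeError("need at least 2 groups")
    tes = [_validate_te(t, e) for t, e in groups]
    all_t = np.concatenate([t for t, _ in tes])
    all_e = np.concatenate([e for _, e in tes])
    grp = np.concatenate([np.full(t.size, gi) for gi, (t, _) in enumerate(tes)])
    event_times = np.unique(all_t[all_e])

    u = np.zeros(k)
    v = np.zeros((k, k))
    for t0 in event_times:
        at_risk = all_t >= t0
        n = int(at_risk.sum())
        d = int((all_e & (all_t == t0)).sum())
        if n == 0 or d == 0:
            continue
        nj = np.array([(at_risk & (grp == gi)).sum() for gi in range(k)], dtype=float)
        dj = np.array([((all_t == t0) & all_e & (grp == gi)).sum() for gi in range(k)],
                      dtype=float)
        w = float(n) if weight == "gehan" else 1.0
        u += w * (dj - d * nj / n)
        if n > 1:
            frac = nj / n
            cov = (np.diag(frac) - np.outer(frac, frac)) * d * (n - d) / (n - 1)
            v += (w ** 2) * cov
    # drop the last group: U sums to zero across groups
    u_red = u[:-1]
    v_red = v[:-1, :-1]
    try:
        chi2 = float(u_red @ np.linalg.solve(v_red, u_red))
    except np.linalg.LinAlgError:
        chi2 = float(u_red @ np.linalg.pinv(v_red) @ u_red)
    chi2 = max(chi2, 0.0)
    df = k - 1
    return chi2, df, float(chi2_dist.sf(chi2, df))


def logrank_test(groups: Sequence[tuple]) -> tuple[float, int, float]:
    """k-sample log-rank test: (chi2, df, p)."""
    return _weighted_logrank(groups, weight="logrank")


def gehan_wilcoxon_test(groups: Sequence[tuple]) -> tuple[float, int, float]:
    """Gehan-Breslow (at-risk-weighted) variant of the log-rank test."""
    return _weighted_logrank(groups, weight="gehan")


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

class Ties(str, enum.Enum):
    EFRON = "efron"
    BRESLOW = "breslow"


@dataclass(frozen=True)
class CoxFit:
    names: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    log_likelihood: float
    ties: Ties
    converged: bool
    iterations: int
    gradient_norm: float

    def summary(self) -> list[dict]:
        return [
            {
                "covariate": name,
                "coef": float(self.coef[i]),
                "se": float(self.se[i]),
                "hr": float(self.hr[i]),
                "ci_low": float(self.ci_low[i]),
                "ci_high": float(self.ci_high[i]),
                "p": float(self.p[i]),
            }
            for i, name in enumerate(self.names)
        ]


def _cox_loglik(beta, x, t, e, ties: Ties):
    """Log partial likelihood, gradient, and negative Hessian.

    Rows must be sorted by ascending time.  Risk-set sums are suffix
    sums; tied deaths are handled per Efron or Breslow.
    """
    n, p = x.shape
    eta = x @ beta
    eta = eta - eta.max()  # guard exp overflow; cancels in ratios
    w = np.exp(eta)
    wx = w[:, None] * x
    wxx = w[:, None, None] * (x[:, :, None] * x[:, None, :])
    # suffix sums over the risk set {i : t_i >= t}
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum(wx[::-1], axis=0)[::-1]
    s2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    loglik = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        deaths = [idx for idx in range(i, j) if e[idx]]
        d = len(deaths)
        if d:
            S0, S1, S2 = s0[i], s1[i], s2[i]
            xd = x[deaths]
            loglik += float(eta[deaths].sum())
            if ties is Ties.BRESLOW or d == 1:
                loglik -= d * np.log(S0)
                grad += xd.sum(axis=0) - d * S1 / S0
                hess += d * (S2 / S0 - np.outer(S1, S1) / S0 ** 2)
            else:  # Efron
                wd = w[deaths].sum()
                wxd = wx[deaths].sum(axis=0)
                wxxd = wxx[deaths].sum(axis=0)
                grad += xd.sum(axis=0)
                for ell in range(d):
                    f = ell / d
                    phi0 = S0 - f * wd
                    phi1 = S1 - f * wxd
                    phi2 = S2 - f * wxxd
                    loglik -= np.log(phi0)
                    grad -= phi1 / phi0
                    hess += phi2 / phi0 - np.outer(phi1, phi1) / phi0 ** 2
        i = j
    return loglik, grad, hess


def cox_fit(
    covariates: np.ndarray,
    times,
    events,
    *,
    names: Sequence[str] | None = None,
    ties: Ties = Ties.EFRON,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CoxFit:
    """Newton-Raphson maximization of the Cox partial likelihood.

    Converges when the gradient max-norm falls below ``tol``.  Monotone
    likelihood (perfect separation) surfaces as ``converged=False``
    rather than a silently huge coefficient.
    """
    x = np.asarray(covariates, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    t, e = _validate_te(times, events)
    n, p = x.shape
    if t.size != n:
        raise FieldRangeError("covariate rows must match times")
    if n <= p:
        raise FieldRangeError("need more subjects than covariates")
    if np.any(x.std(axis=0) == 0):
        raise FieldRangeError("constant covariate")
    if names is None:
        names = tuple(f"x{i}" for i in range(p))
    else:
        names = tuple(names)

    order = np.argsort(t, kind="stable")
    xs, ts, es = x[order], t[order], e[order]

    beta = np.zeros(p)
    loglik, grad, hess = _cox_loglik(beta, xs, ts, es, ties)
    gnorm = float(np.abs(grad).max())
    converged = gnorm < tol
    it = 0
    while not converged and it < max_iter:
        it += 1
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        # step-halving to guarantee ascent
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, g_new, h_new = _cox_loglik(cand, xs, ts, es, ties)
            if np.isfinite(ll_new) and ll_new >= loglik - 1e-12:
                break
            scale /= 2.0
        beta, loglik, grad, hess = cand, ll_new, g_new, h_new
        gnorm = float(np.abs(grad).max())
        if gnorm < tol:
            converged = True
        if np.abs(beta).max() > 50:
            break
    if np.abs(beta).max() > 20:
        converged = False  # monotone likelihood / separation

    cov = np.linalg.pinv(hess)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        z = np.where(se > 0, beta / se, np.inf * np.sign(beta))
        pvals = 2 * norm.sf(np.abs(z))
        ci_low = np.exp(beta - 1.959963984540054 * se)
        ci_high = np.exp(beta + 1.959963984540054 * se)
    return CoxFit(
        names=names,
        coef=beta,
        se=se,
        hr=np.exp(beta),
        ci_low=ci_low,
        ci_high=ci_high,
        p=pvals,
        log_likelihood=float(loglik),
        ties=ties,
        converged=converged,
        iterations=it,
        gradient_norm=gnorm,
    )


# ---------------------------------------------------------------------------
# Cohort-level report
# ---------------------------------------------------------------------------

#: Covariate codings used in the multivariate model: age >= 70, male sex,
#: stage III/IV, squamous-differentiation histology, and expression type
#: collapsed to transitional/basal-like vs classical.
COVARIATE_NAMES = ("age_ge70", "sex_male", "stage_3_4", "histology_sq_diff",
                   "expression_type")


def _case_pattern(case, assignment) -> Pattern:
    if assignment is not None:
        pattern = assignment.get(case.case_id)
    else:
        pattern = case.latent_pattern
    if pattern is None:
        raise FieldRangeError(f"case {case.case_id}: no pattern available")
    return pattern


def _covariate_row(case, assignment) -> dict[str, float]:
    return {
        "age_ge70": float(case.age_years >= 70),
        "sex_male": float(case.sex.value == "M"),
        "stage_3_4": float(case.stage in (Stage.III, Stage.IV)),
        "histology_sq_diff": float(case.histology.value == "sq_diff"),
        "expression_type": float(_case_pattern(case, assignment)
                                 is not Pattern.CLASSICAL),
    }


def run_survival_analysis(
    cohort: Cohort,
    grouping: str = "pattern",
    adjusters: Sequence[str] = COVARIATE_NAMES,
    *,
    assignment: Mapping[str, Pattern] | None = None,
    ties: Ties = Ties.EFRON,
    glandular_only: bool = False,
) -> dict:
    """KM curves per group, log-rank and Wilcoxon p, univariate Cox per
    factor, and the multivariate Cox model.

    ``grouping`` is ``"pattern"`` (three IHC patterns) or ``"ck56_pos"``
    (CK5/6 grade >= 1 vs 0, optionally restricted to glandular
    histology via ``glandular_only``).  Models including stage exclude
    stage-unknown cases.
    """
    cases = list(cohort.cases)
    if glandular_only:
        cases = [c for c in cases if c.histology.value == "glandular"]
    if not cases:
        raise FieldRangeError("no cases after filtering")

    if grouping == "pattern":
        key = lambda c: _case_pattern(c, assignment).value
        order = [p.value for p in Pattern]
    elif grouping == "ck56_pos":
        key = lambda c: ("positive" if c.stains[Marker.CK56.value].grade >= 1
                         else "negative")
        order = ["negative", "positive"]
    else:
        raise FieldRangeError(f"unknown grouping {grouping!r}")

    groups: dict[str, list] = {}
    for c in cases:
        groups.setdefault(key(c), []).append(c)
    group_levels = [g for g in order if g in groups]
    if len(group_levels) < 2:
        raise FieldRangeError("fewer than 2 non-empty groups")

    km = {}
    te = []
    for g in group_levels:
        times = [c.time_days for c in groups[g]]
        events = [c.event for c in groups[g]]
        curve = km_estimate(times, events)
        km[g] = {
            "n": len(times),
            "events": int(sum(events)),
            "times": curve.times.tolist(),
            "survival": curve.survival.tolist(),
            "at_risk": curve.at_risk.tolist(),
        }
        te.append((np.array(times), np.array(events, dtype=bool)))

    lr_chi2, lr_df, lr_p = logrank_test(te)
    wx_chi2, wx_df, wx_p = gehan_wilcoxon_test(te)

    def _fit(names: Sequence[str]) -> dict:
        use = cases
        if "stage_3_4" in names:
            use = [c for c in use if c.stage is not Stage.UNKNOWN]
        rows = [_covariate_row(c, assignment) for c in use]
        xmat = np.array([[r[nm] for nm in names] for r in rows])
        # subgroup analyses can leave a covariate constant (e.g. histology
        # within the glandular-only restriction): drop it, don't crash
        keep = [i for i in range(xmat.shape[1]) if xmat[:, i].std() > 0]
        dropped = [names[i] for i in range(xmat.shape[1]) if i not in keep]
        if not keep:
            raise FieldRangeError("all covariates constant after filtering")
        fit = cox_fit(xmat[:, keep],
                      np.array([c.time_days for c in use]),
                      np.array([c.event for c in use], dtype=bool),
                      names=[names[i] for i in keep], ties=ties)
        return {"n": len(use), "converged": fit.converged,
                "dropped_constant": dropped, "covariates": fit.summary()}

    univariate = {nm: _fit([nm]) for nm in adjusters
                  if any(_covariate_row(c, assignment)[nm] !=
                         _covariate_row(cases[0], assignment)[nm]
                         for c in cases)}
    multivariate = _fit(list(adjusters))

    return {
        "grouping": grouping,
        "groups": km,
        "logrank": {"chi2": lr_chi2, "df": lr_df, "p": lr_p},
        "wilcoxon_gehan": {"chi2": wx_chi2, "df": wx_df, "p": wx_p},
        "cox_ties": ties.value,
        "univariate": univariate,
        "multivariate": multivariate,
    }
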