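"""Kaplan–Meier estimation, log-rank tests and Cox proportional-hazards models.

The Cox partial likelihood is maximized by Newton–Raphson with a
step-halving guard (the log-likelihood never decreases across accepted
iterations), Efron tie-handling by default and Breslow available.  The
score test at beta = 0 with Breslow ties reproduces the two-group log-rank
statistic exactly when event times are untied, which anchors both
implementations to each other.  Wald confidence intervals and p-values are
reported per covariate, as in the standard univariate/multivariate
survival tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .errors import ConvergenceError, ValidationError
from .io import TestResult

__all__ = [
    "KMCurve", "CoxResult", "CoxTerm", "km_estimate", "logrank_test",
    "cox_fit", "cox_score_test", "backward_select", "BackwardSelection",
    "interaction_analysis", "InteractionResult",
]

_Z975 = 1.959963984540054  # Phi^{-1}(0.975)


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Product-limit estimate on the grid of observed event times."""

    times: np.ndarray          # distinct event times, ascending
    survival: np.ndarray       # S(t) just after each event time
    at_risk: np.ndarray        # risk-set size just before each event time
    n_events: np.ndarray       # deaths at each event time
    censor_times: np.ndarray   # times of censored observations

    def __post_init__(self) -> None:
        s = np.asarray(self.survival, float)
        if s.size and (np.any(np.diff(s) > 1e-12) or s.min() < -1e-12
                       or s.max() > 1 + 1e-12):
            raise ValidationError("survival estimates must be nonincreasing in [0,1]")

    def survival_at(self, t: float) -> float:
        """S(t); 1 before the first event."""
        idx = np.searchsorted(self.times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "survival": self.survival,
                             "at_risk": self.at_risk, "n_events": self.n_events})


def _check_survival_input(times, events) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValidationError("empty survival data")
    if times.shape != events.shape:
        raise ValidationError("times and events must align")
    if not np.all(np.isfinite(times)) or np.any(times < 0):
        raise ValidationError("times must be finite and nonnegative")
    return times, events


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> KMCurve:
    """Product-limit survival estimator.

    A censoring time tied with an event time is treated as censored just
    after the event (the subject is in the risk set for that event).
    """
    times, events = _check_survival_input(times, events)
    event_times = np.unique(times[events])
    n = times.size
    surv = []
    risk = []
    deaths = []
    s = 1.0
    for t in event_times:
        at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & events))
        s *= 1.0 - d / at_risk
        surv.append(s)
        risk.append(at_risk)
        deaths.append(d)
    return KMCurve(times=event_times, survival=np.array(surv),
                   at_risk=np.array(risk, dtype=int),
                   n_events=np.array(deaths, dtype=int),
                   censor_times=np.sort(times[~events]))


def logrank_test(times: Sequence[float], events: Sequence[bool],
                 group: Sequence[int]) -> TestResult:
    """Two-group log-rank test (O - E with hypergeometric variance, df = 1)."""
    times, events = _check_survival_input(times, events)
    group = np.asarray(group)
    uniq = np.unique(group)
    if uniq.size != 2:
        raise ValidationError(f"log-rank needs exactly 2 groups, got {uniq.size}")
    g1 = group == uniq[1]
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & g1).sum())
        dead = (times == t) & events
        d = int(dead.sum())
        d1 = int((dead & g1).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        stat, p = 0.0, 1.0
    else:
        stat = o_minus_e ** 2 / var
        p = float(spstats.chi2.sf(stat, 1))
    return TestResult(statistic=float(stat), p_value=p, df=1.0,
                      method="log-rank test",
                      extras={"observed_minus_expected": float(o_minus_e)})


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

@dataclass
class CoxTerm:
    name: str
    coef: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    p: float

    def __post_init__(self) -> None:
        if not np.isclose(self.hr, np.exp(self.coef)):
            raise ValidationError("HR must equal exp(coef)")
        if not (self.ci_low <= self.hr <= self.ci_high):
            raise ValidationError("CI bounds must bracket the HR")

    def to_dict(self) -> dict:
        return {k: float(getattr(self, k))
                for k in ("coef", "se", "hr", "ci_low", "ci_high", "p")}


@dataclass
class CoxResult:
    """Fitted proportional-hazards model: per-covariate terms plus fit metadata."""

    terms: dict[str, CoxTerm]
    loglik: float
    loglik_null: float
    n: int
    n_events: int
    n_dropped: int
    n_iter: int
    ties: str
    loglik_trace: list[float] = field(default_factory=list)
    notes: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> CoxTerm:
        return self.terms[name]

    def to_dict(self) -> dict:
        return {
            "terms": {k: t.to_dict() for k, t in self.terms.items()},
            "loglik": float(self.loglik),
            "loglik_null": float(self.loglik_null),
            "n": self.n, "n_events": self.n_events,
            "n_dropped": self.n_dropped, "n_iter": self.n_iter,
            "ties": self.ties, "notes": dict(self.notes),
        }


class _PartialLikelihood:
    """Efron/Breslow partial likelihood with analytic gradient and Hessian."""

    def __init__(self, X: np.ndarray, times: np.ndarray, events: np.ndarray,
                 ties: str):
        order = np.argsort(-times, kind="mergesort")  # descending time
        self.X = X[order]
        self.times = times[order]
        self.events = events[order]
        self.ties = ties
        # contiguous blocks of equal time in the descending ordering
        boundaries = np.flatnonzero(np.diff(self.times)) + 1
        self.blocks = np.split(np.arange(self.times.size),
                               boundaries)

    def evaluate(self, beta: np.ndarray
                 ) -> tuple[float, np.ndarray, np.ndarray]:
        """(loglik, gradient, information) at beta."""
        X, events = self.X, self.events
        p = X.shape[1]
        eta = X @ beta
        eta = eta - eta.max()  # guard overflow; cancels in ratios and loglik diffs
        w = np.exp(eta)
        wX = w[:, None] * X
        wXX = np.einsum("i,ij,ik->ijk", w, X, X)
        cw = np.cumsum(w)
        cwX = np.cumsum(wX, axis=0)
        cwXX = np.cumsum(wXX, axis=0)
        ll = 0.0
        grad = np.zeros(p)
        info = np.zeros((p, p))
        for block in self.blocks:
            dead = block[events[block]]
            d = dead.size
            if d == 0:
                continue
            end = block[-1]
            s0 = cw[end]
            s1 = cwX[end]
            s2 = cwXX[end]
            ll += eta[dead].sum()
            grad += X[dead].sum(axis=0)
            if self.ties == "breslow" or d == 1:
                ll -= d * np.log(s0)
                grad -= d * s1 / s0
                info += d * (s2 / s0 - np.outer(s1, s1) / s0 ** 2)
            else:  # efron
                wd = w[dead].sum()
                s1d = wX[dead].sum(axis=0)
                s2d = wXX[dead].sum(axis=0)
                for l in range(d):
                    f = l / d
                    s0l = s0 - f * wd
                    s1l = s1 - f * s1d
                    s2l = s2 - f * s2d
                    ll -= np.log(s0l)
                    grad -= s1l / s0l
                    info += s2l / s0l - np.outer(s1l, s1l) / s0l ** 2
        return float(ll), grad, info


def _prepare_design(covariates: pd.DataFrame, times, events
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str], int]:
    if not isinstance(covariates, pd.DataFrame):
        covariates = pd.DataFrame(np.asarray(covariates, dtype=float))
        covariates.columns = [f"x{i}" for i in range(covariates.shape[1])]
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if covariates.shape[0] != times.size or times.size != events.size:
        raise ValidationError("covariates, times and events must align")
    X = covariates.to_numpy(dtype=float)
    keep = np.all(np.isfinite(X), axis=1) & np.isfinite(times)
    n_dropped = int((~keep).sum())
    X, times, events = X[keep], times[keep], events[keep]
    if np.any(times < 0):
        raise ValidationError("negative survival time")
    if X.shape[0] == 0:
        raise ValidationError("no complete cases")
    if events.sum() < 1:
        raise ValidationError("no events in the data")
    names = [str(c) for c in covariates.columns]
    for j, name in enumerate(names):
        if np.ptp(X[:, j]) == 0:
            raise ValidationError(f"constant covariate {name!r}")
    return X, times, events, names, n_dropped


def cox_fit(covariates: pd.DataFrame, times: Sequence[float],
            events: Sequence[bool], ties: str = "efron",
            tol: float = 1e-9, max_iter: int = 100) -> CoxResult:
    """Maximize the Cox partial likelihood by guarded Newton–Raphson.

    Convergence is declared when the largest coefficient change falls below
    ``tol``.  Rows with missing covariate values are dropped (complete-case)
    and counted in ``n_dropped``.  Monotone likelihoods (complete separation)
    raise :class:`ConvergenceError` naming the runaway covariate.
    """
    if ties not in ("efron", "breslow"):
        raise ValidationError(f"unknown ties method {ties!r}")
    X, times_a, events_a, names, n_dropped = _prepare_design(
        covariates, times, events)
    # standardize internally for numerical conditioning; invert at the end
    scale = X.std(axis=0)
    Xs = (X - X.mean(axis=0)) / scale
    pl = _PartialLikelihood(Xs, times_a, events_a, ties)
    p = Xs.shape[1]
    beta = np.zeros(p)
    ll, grad, info = pl.evaluate(beta)
    ll_null = ll
    trace = [ll]
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            raise ConvergenceError(
                "singular information matrix (collinear covariates?)"
            ) from None
        # step-halving: never accept a decrease in the partial log-likelihood
        factor = 1.0
        for _ in range(40):
            cand = beta + factor * step
            ll_new, grad_new, info_new = pl.evaluate(cand)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        else:
            if np.max(np.abs(beta)) > 5:
                worst = names[int(np.argmax(np.abs(beta)))]
                raise ConvergenceError(
                    f"monotone likelihood: coefficient for {worst!r} diverges "
                    "(complete separation?)"
                )
            raise ConvergenceError(
                f"step-halving failed to improve the likelihood at iteration "
                f"{n_iter}; trace={trace[-5:]}"
            )
        delta = np.max(np.abs(cand - beta))
        beta, ll, grad, info = cand, ll_new, grad_new, info_new
        trace.append(ll)
        if np.max(np.abs(beta)) > 200:
            worst = names[int(np.argmax(np.abs(beta)))]
            raise ConvergenceError(
                f"monotone likelihood: coefficient for {worst!r} diverges "
                "(complete separation?)"
            )
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"no convergence in {max_iter} iterations; loglik trace={trace[-5:]}"
        )
    cov = np.linalg.inv(info)
    beta_orig = beta / scale
    se_orig = np.sqrt(np.diag(cov)) / scale
    terms = {}
    for j, name in enumerate(names):
        b, se = float(beta_orig[j]), float(se_orig[j])
        z2 = (b / se) ** 2
        terms[name] = CoxTerm(
            name=name, coef=b, se=se, hr=float(np.exp(b)),
            ci_low=float(np.exp(b - _Z975 * se)),
            ci_high=float(np.exp(b + _Z975 * se)),
            p=float(spstats.chi2.sf(z2, 1)),
        )
    return CoxResult(terms=terms, loglik=ll, loglik_null=ll_null,
                     n=int(Xs.shape[0]), n_events=int(events_a.sum()),
                     n_dropped=n_dropped, n_iter=n_iter, ties=ties,
                     loglik_trace=trace)


def cox_score_test(covariates: pd.DataFrame, times: Sequence[float],
                   events: Sequence[bool], ties: str = "breslow") -> TestResult:
    """Score (Rao) test of beta = 0 for the Cox partial likelihood."""
    X, times_a, events_a, names, _ = _prepare_design(covariates, times, events)
    pl = _PartialLikelihood(X, times_a, events_a, ties)
    _, grad, info = pl.evaluate(np.zeros(X.shape[1]))
    stat = float(grad @ np.linalg.solve(info, grad))
    df = X.shape[1]
    return TestResult(statistic=stat, p_value=float(spstats.chi2.sf(stat, df)),
                      df=float(df), method=f"Cox score test ({ties} ties)")


# ---------------------------------------------------------------------------
# Variable selection
# ---------------------------------------------------------------------------

@dataclass
class BackwardSelection:
    """Outcome of backward elimination on Wald p-values."""

    final: CoxResult | None
    dropped: list[tuple[str, float]]
    retained: list[str]
    retain_p: float

    def to_dict(self) -> dict:
        return {
            "procedure": "backward elimination on Wald p",
            "retain_p": float(self.retain_p),
            "dropped": [[name, float(p)] for name, p in self.dropped],
            "retained": list(self.retained),
            "final": None if self.final is None else self.final.to_dict(),
        }


def backward_select(covariates: pd.DataFrame, times: Sequence[float],
                    events: Sequence[bool], retain_p: float = 0.05,
                    force_in: Sequence[str] = (), ties: str = "efron",
                    ) -> BackwardSelection:
    """Iteratively drop the eligible covariate with the largest Wald p > retain_p.

    Covariates in ``force_in`` are never dropped.  When every candidate is
    eliminated the result carries ``final=None``.
    """
    if covariates.shape[1] < 1:
        raise ValidationError("backward_select needs at least one candidate")
    current = list(covariates.columns)
    forced = set(force_in)
    unknown = forced - set(current)
    if unknown:
        raise ValidationError(f"force_in names not among candidates: {sorted(unknown)}")
    dropped: list[tuple[str, float]] = []
    fit: CoxResult | None = None
    while current:
        fit = cox_fit(covariates[current], times, events, ties=ties)
        eligible = {name: fit[name].p for name in current if name not in forced}
        if not eligible:
            break
        worst, worst_p = max(eligible.items(), key=lambda kv: kv[1])
        if worst_p <= retain_p:
            break
        dropped.append((worst, worst_p))
        current.remove(worst)
        fit = None
    if fit is None and current:
        fit = cox_fit(covariates[current], times, events, ties=ties)
    return BackwardSelection(final=fit if current else None, dropped=dropped,
                             retained=list(current), retain_p=retain_p)


# ---------------------------------------------------------------------------
# Chemotherapy interaction
# ---------------------------------------------------------------------------

@dataclass
class InteractionResult:
    """Per-subtype chemotherapy models plus the pooled interaction model."""

    stratum_models: dict[str, CoxResult | None]
    interaction_model: CoxResult | None
    interaction_term: str = "cod_x_chemo"
    error: str | None = None

    @property
    def interaction_p(self) -> float | None:
        if self.interaction_model is None:
            return None
        return self.interaction_model[self.interaction_term].p

    def stratum_hr(self, subtype: str) -> float | None:
        model = self.stratum_models.get(subtype)
        return None if model is None else model["chemo"].hr

    def to_dict(self) -> dict:
        return {
            "stratum_models": {k: (None if m is None else m.to_dict())
                               for k, m in self.stratum_models.items()},
            "interaction_model": (None if self.interaction_model is None
                                  else self.interaction_model.to_dict()),
            "interaction_term": self.interaction_term,
            "error": self.error,
        }


def interaction_analysis(subtypes: Sequence[str], chemo: Sequence[bool],
                         times: Sequence[float], events: Sequence[bool],
                         ties: str = "efron") -> InteractionResult:
    """Treatment-by-subtype analysis.

    Fits (i) a chemotherapy-only Cox model within each subtype stratum and
    (ii) a pooled model with subtype, chemotherapy and their product term.
    Strata lacking both treatment arms (or events) are reported as absent;
    the pooled model requires all four subtype x treatment cells nonempty.
    """
    subtypes = np.asarray(subtypes)
    chemo_a = np.asarray(chemo, dtype=bool)
    times_a = np.asarray(times, dtype=float)
    events_a = np.asarray(events, dtype=bool)
    bad = sorted(set(subtypes.tolist()) - {"INT", "COD"})
    if bad:
        raise ValidationError(f"subtype labels must be INT or COD; got {bad}")
    stratum: dict[str, CoxResult | None] = {}
    for s in ("INT", "COD"):
        mask = subtypes == s
        if mask.sum() == 0 or len(set(chemo_a[mask].tolist())) < 2 \
                or events_a[mask].sum() == 0:
            stratum[s] = None
            continue
        design = pd.DataFrame({"chemo": chemo_a[mask].astype(float)})
        try:
            stratum[s] = cox_fit(design, times_a[mask], events_a[mask], ties=ties)
        except (ValidationError, ConvergenceError):
            stratum[s] = None
    cod = (subtypes == "COD").astype(float)
    cells = {(int(c), int(t)) for c, t in zip(cod, chemo_a)}
    error = None
    pooled: CoxResult | None = None
    if len(cells) < 4:
        error = ("interaction model needs all four subtype x chemotherapy "
                 f"cells nonempty; present: {sorted(cells)}")
    else:
        design = pd.DataFrame({
            "cod": cod,
            "chemo": chemo_a.astype(float),
            "cod_x_chemo": cod * chemo_a,
        })
        try:
            pooled = cox_fit(design, times_a, events_a, ties=ties)
        except (ValidationError, ConvergenceError) as exc:
            error = str(exc)
    return InteractionResult(stratum_models=stratum, interaction_model=pooled,
                             error=error)
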