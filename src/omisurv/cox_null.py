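"""Covariate-only Cox proportional hazards null model.

The association tests never fit the microbiome; they only need the null
model lambda_i(t) = lambda_0(t) * exp(sum_k alpha_k X_ik), its per-subject
cumulative hazard at the observed time, and the martingale residuals
r_i = delta_i - Lambda_hat_i. Tied event times are handled with Efron's
approximation by default (Breslow available for cross-checking); the
Efron cumulative-hazard plug-in is the one used by standard survival
software: a subject dying in a tie of size d receives the fractional
increments (1 - l/d) / (S0 - (l/d) * Sd0), l = 0..d-1, while subjects who
remain at risk receive the full increments 1 / (S0 - (l/d) * Sd0). With
this convention the residuals sum to zero exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConvergenceError, DegenerateDataError, ValidationError
from .io_formats import SurvivalData

MAX_ITER = 50
SCORE_TOL = 1e-9


@dataclass
class NullFit:
    """Result of fitting the covariate-only Cox model."""

    alpha: np.ndarray          # (q,) covariate coefficients; empty when q = 0
    cumhaz: np.ndarray         # (n,) estimated cumulative hazard at Y_i
    residuals: np.ndarray      # (n,) martingale residuals d - Lambda_hat
    event_times: np.ndarray    # ordered distinct event times tau_1..tau_m
    risk_set_sizes: np.ndarray  # subjects at risk at each tau_g
    ties: str = "efron"
    n_iter: int = 0
    covariate_names: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.residuals)


def _group_structure(t, d):
    """Distinct event times, their tied-death index lists and risk-set starts."""
    ev_times = np.unique(t[d])
    starts = np.searchsorted(t, ev_times, side="left")
    death_idx = [np.flatnonzero(d & (t == tau)) for tau in ev_times]
    return ev_times, starts, death_idx


def _loglik_score_hess(beta, Xs, t, d, ev_times, starts, death_idx, ties):
    n, q = Xs.shape
    eta = Xs @ beta if q else np.zeros(n)
    w = np.exp(eta)
    wx = w[:, None] * Xs
    # suffix sums give risk-set aggregates for the ascending time order
    S0suf = np.cumsum(w[::-1])[::-1]
    S1suf = np.cumsum(wx[::-1], axis=0)[::-1]
    wxx = wx[:, :, None] * Xs[:, None, :]
    S2suf = np.cumsum(wxx[::-1], axis=0)[::-1]
    ll = 0.0
    score = np.zeros(q)
    hess = np.zeros((q, q))
    for g, tau in enumerate(ev_times):
        s = starts[g]
        dead = death_idx[g]
        dd = len(dead)
        S0, S1, S2 = S0suf[s], S1suf[s], S2suf[s]
        ll += eta[dead].sum()
        score += Xs[dead].sum(axis=0)
        if ties == "efron" and dd > 1:
            f = np.arange(dd) / dd
        else:
            f = np.zeros(dd)
        Sd0 = w[dead].sum()
        Sd1 = wx[dead].sum(axis=0)
        Sd2 = wxx[dead].sum(axis=0)
        phi0 = S0 - f * Sd0
        phi1 = S1[None, :] - f[:, None] * Sd1[None, :]
        phi2 = S2[None, :, :] - f[:, None, None] * Sd2[None, :, :]
        ll -= np.log(phi0).sum()
        score -= (phi1 / phi0[:, None]).sum(axis=0)
        hess -= (phi2 / phi0[:, None, None]).sum(axis=0)
        hess += np.einsum("li,lj->ij", phi1 / phi0[:, None], phi1 / phi0[:, None])
    return ll, score, hess


def _expected_events(beta, Xs, t, d, ev_times, starts, death_idx, ties):
    """Per-subject cumulative hazard (expected event count) at the observed time."""
    n, q = Xs.shape
    eta = Xs @ beta if q else np.zeros(n)
    w = np.exp(eta)
    S0suf = np.cumsum(w[::-1])[::-1]
    E = np.zeros(n)
    cum_full = 0.0
    for g, tau in enumerate(ev_times):
        s = starts[g]
        dead = death_idx[g]
        dd = len(dead)
        S0 = S0suf[s]
        if ties == "efron":
            f = np.arange(dd) / dd
            Sd0 = w[dead].sum()
        else:
            f = np.zeros(dd)
            Sd0 = 0.0
        phi0 = S0 - f * Sd0
        h_full = float(np.sum(1.0 / phi0))
        h_death = float(np.sum((1.0 - f) / phi0))
        # subjects leaving the risk set strictly between this tau and the next
        # accumulate everything up to and including this increment
        nxt = starts[g + 1] if g + 1 < len(ev_times) else n
        leaving = np.arange(s, nxt)
        leaving = leaving[~np.isin(leaving, dead)]
        E[leaving] = w[leaving] * (cum_full + h_full)
        E[dead] = w[dead] * (cum_full + h_death)
        cum_full += h_full
    # subjects censored before the first event time keep E = 0 (already zero)
    return E


def fit_null_model(surv: SurvivalData, ties: str = "efron") -> NullFit:
    """Fit the covariate-only Cox model by Newton-Raphson on the partial
    likelihood and return coefficients, cumulative hazards and residuals.

    With no covariates the cumulative hazard reduces to the (Efron-adjusted)
    Nelson-Aalen estimator evaluated at each subject's observed time.
    """
    if ties not in ("efron", "breslow"):
        raise ValidationError(f"unknown tie handling: {ties!r}")
    if surv.n_events == 0:
        raise DegenerateDataError("no events observed; cannot fit null model")
    if surv.n_events < 2:
        raise DegenerateDataError("at least 2 events are required")
    n, q = surv.n, surv.q
    X = surv.covariates if q else np.zeros((n, 0))
    if q and np.linalg.matrix_rank(X - X.mean(axis=0)) < q:
        raise ValidationError("covariate matrix is rank-deficient after centering")

    order = np.argsort(surv.time, kind="stable")
    t = surv.time[order]
    d = surv.event[order].astype(bool)
    Xs = X[order]
    ev_times, starts, death_idx = _group_structure(t, d)

    beta = np.zeros(q)
    n_iter = 0
    if q:
        ll, score, hess = _loglik_score_hess(beta, Xs, t, d, ev_times, starts,
                                             death_idx, ties)
        for n_iter in range(1, MAX_ITER + 1):
            if np.max(np.abs(score)) < SCORE_TOL:
                break
            step = np.linalg.solve(hess, score)
            new_beta = beta - step
            new = _loglik_score_hess(new_beta, Xs, t, d, ev_times, starts,
                                     death_idx, ties)
            halves = 0
            while new[0] < ll - 1e-12 and halves < 20:  # step-halving
                step /= 2.0
                new_beta = beta - step
                new = _loglik_score_hess(new_beta, Xs, t, d, ev_times, starts,
                                         death_idx, ties)
                halves += 1
            beta = new_beta
            ll, score, hess = new
        else:
            raise ConvergenceError(
                f"Newton-Raphson did not converge in {MAX_ITER} iterations; "
                f"max |score| = {np.max(np.abs(score)):.3g}"
            )

    E_sorted = _expected_events(beta, Xs, t, d, ev_times, starts, death_idx, ties)
    cumhaz = np.empty(n)
    cumhaz[order] = E_sorted
    residuals = surv.event.astype(float) - cumhaz
    risk_sizes = n - starts
    return NullFit(
        alpha=beta,
        cumhaz=cumhaz,
        residuals=residuals,
        event_times=ev_times,
        risk_set_sizes=risk_sizes,
        ties=ties,
        n_iter=n_iter,
        covariate_names=list(surv.covariate_names),
    )


def martingale_residuals(fit: NullFit) -> np.ndarray:
    """The residual vector d - Lambda_hat on which all score statistics act."""
    return fit.residuals.copy()
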