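"""Hierarchical random-effects fitting and comparison of the learning models.

Per-subject parameters are MAP estimates under a Gaussian raw-space prior;
model evidence comes from a Laplace approximation at the MAP. The
hierarchical loop alternates (E) per-subject fits and evidence-based
responsibilities with (M) responsibility-weighted updates of each model's
group mean, group variance, and Dirichlet pseudo-counts over model
frequencies. Model comparison reports exceedance probabilities (Monte Carlo
over the Dirichlet), the Bayesian omnibus risk (variational free-energy
comparison against the equal-frequency null), and the protected exceedance
probability pxp_k = xp_k * (1 - bor) + bor / K.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import digamma, expit, gammaln, logsumexp
from scipy.stats import t as student_t

from .data import SubjectData
from .models import PRIOR_MEAN, PRIOR_VAR, MODEL_SPECS, DesignBuilder

logger = logging.getLogger(__name__)

OBJECTIVE_FLOOR = -1e20  # log-posterior values are clipped here


class _SubjectModelProblem:
    """Negative log posterior of one (subject, model) pair, with all
    parameter-free structure cached."""

    def __init__(self, model_id: int, data: SubjectData):
        self.model_id = model_id
        self.spec = MODEL_SPECS[model_id]
        self.builder = DesignBuilder(model_id, data.sequence,
                                     rt_ms=data.rt_ms, accuracy=data.accuracy)
        self.y = data.rt_ms[self.builder.included] / 1000.0  # seconds
        self.d = self.spec.n_params
        self.n_nonlinear = len(self.spec.nonlinear_names)
        self._nl_info = [(n, n.startswith("b_"))
                         for n in self.spec.nonlinear_names]
        self._nat: dict[str, float] = {}
        n = len(self.y)
        self._ll_const = -(n / 2.0) * (1.0 + math.log(2.0 * math.pi))
        self._half_n = n / 2.0

    def log_post(self, raw: np.ndarray, prior_mean: np.ndarray,
                 prior_var: np.ndarray) -> float:
        nat = self._nat
        for i, (name, is_rate) in enumerate(self._nl_info):
            v = min(max(raw[i], -600.0), 600.0)
            nat[name] = math.exp(v) if is_rate else 1.0 / (1.0 + math.exp(-v))
        X = self.builder.matrix_values(nat)
        r = self.y - X @ raw[self.n_nonlinear:]
        rss = float(r @ r)
        if rss <= 0.0 or not np.isfinite(rss):
            return OBJECTIVE_FLOOR
        ll = self._ll_const - self._half_n * math.log(rss / len(self.y))
        dev = raw - prior_mean
        lp = -0.5 * float(np.sum(dev * dev / prior_var)) \
            - 0.5 * float(np.sum(np.log(2.0 * np.pi * prior_var)))
        val = ll + lp
        if not np.isfinite(val):
            return OBJECTIVE_FLOOR
        return max(val, OBJECTIVE_FLOOR)

    def neg_log_post_grad(self, raw: np.ndarray, prior_mean: np.ndarray,
                          prior_var: np.ndarray
                          ) -> tuple[float, np.ndarray]:
        """Negative log posterior and its analytic gradient.

        Beta gradient: -(n/RSS) X' r + (beta - m)/v. Each nonlinear
        parameter enters through exactly one standardized column whose
        derivative the design builder supplies; the chain rule adds the
        transform Jacobian (exp for rates, sigmoid derivative for alpha).
        """
        nn = self.n_nonlinear
        nat = self._nat
        dnat = np.empty(nn)
        for i, (name, is_rate) in enumerate(self._nl_info):
            v = min(max(raw[i], -600.0), 600.0)
            if is_rate:
                nat[name] = math.exp(v)
                dnat[i] = nat[name]
            else:
                a = 1.0 / (1.0 + math.exp(-v))
                nat[name] = a
                dnat[i] = a * (1.0 - a)
        X, col_grads = self.builder.matrix_values_grad(nat)
        betas = raw[nn:]
        r = self.y - X @ betas
        rss = float(r @ r)
        if rss <= 0.0 or not np.isfinite(rss):
            return -OBJECTIVE_FLOOR, np.zeros(self.d)
        n = len(self.y)
        f = -self._ll_const + self._half_n * math.log(rss / n)
        dev = raw - prior_mean
        f += 0.5 * float(np.sum(dev * dev / prior_var)) \
            + 0.5 * float(np.sum(np.log(2.0 * np.pi * prior_var)))
        if not np.isfinite(f):
            return -OBJECTIVE_FLOOR, np.zeros(self.d)
        g = np.empty(self.d)
        coef = n / rss
        g[nn:] = -coef * (X.T @ r) + dev[nn:] / prior_var[nn:]
        for i, (name, _) in enumerate(self._nl_info):
            j, dz = col_grads[name]
            g[i] = (-coef * betas[j] * float(dz @ r)) * dnat[i] \
                + dev[i] / prior_var[i]
        return min(f, -OBJECTIVE_FLOOR), g


def _numeric_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    d = len(x)
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((d, d))
    f0 = f(x)
    fp = np.empty(d)
    fm = np.empty(d)
    for i in range(d):
        ei = np.zeros(d); ei[i] = h[i]
        fp[i] = f(x + ei)
        fm[i] = f(x - ei)
        H[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / h[i] ** 2
    for i in range(d):
        ei = np.zeros(d); ei[i] = h[i]
        for j in range(i + 1, d):
            ej = np.zeros(d); ej[j] = h[j]
            fpp = f(x + ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fp[i] - fp[j] + 2.0 * f0
                                 - fm[i] - fm[j] + fmm) / (2.0 * h[i] * h[j])
    return H


def _hessian_from_grad(grad_f, x: np.ndarray,
                       rel_step: float = 1e-5) -> np.ndarray:
    """Central differences of an analytic gradient."""
    d = len(x)
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((d, d))
    for i in range(d):
        ei = np.zeros(d); ei[i] = h[i]
        H[:, i] = (grad_f(x + ei) - grad_f(x - ei)) / (2.0 * h[i])
    return 0.5 * (H + H.T)


@dataclass
class MAPFit:
    """Regularized per-subject fit of one model."""

    model_id: int
    raw: np.ndarray
    log_posterior: float
    log_evidence: float
    cov: np.ndarray          # Laplace posterior covariance
    converged: bool
    hessian_regularized: bool = False

    @property
    def posterior_sd(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def _laplace(problem: _SubjectModelProblem, raw: np.ndarray, lp: float,
             grad_f) -> tuple[float, np.ndarray, bool]:
    """Laplace log evidence and posterior covariance at the MAP."""
    d = problem.d
    H = _hessian_from_grad(grad_f, raw)
    w, V = np.linalg.eigh(H)
    regularized = bool(np.any(w <= 1e-10))
    if regularized:
        w = np.maximum(w, 1e-6)
        logger.warning("model %d: singular Hessian regularized at the MAP",
                       problem.model_id)
    logdet = float(np.sum(np.log(w)))
    cov = (V * (1.0 / w)) @ V.T
    log_ev = lp + 0.5 * d * np.log(2.0 * np.pi) - 0.5 * logdet
    return float(log_ev), cov, regularized


def fit_subject_map(model_id: int, data: SubjectData,
                    prior_mean=None, prior_var=None, *,
                    n_restarts: int = 8,
                    rng: np.random.Generator | None = None,
                    extra_starts=None) -> MAPFit:
    """MAP estimate and Laplace evidence for one subject under one model.

    The posterior combines the profiled-sigma Gaussian GLM likelihood with an
    independent Normal prior per raw parameter (default N(0, 6.25)).
    Optimization is multi-start quasi-Newton: the prior mean, any
    ``extra_starts`` (warm starts), and ``n_restarts`` draws from the prior.
    """
    problem = _SubjectModelProblem(model_id, data)
    d = problem.d
    prior_mean = np.broadcast_to(
        np.asarray(PRIOR_MEAN if prior_mean is None else prior_mean, float),
        (d,)).copy()
    prior_var = np.broadcast_to(
        np.asarray(PRIOR_VAR if prior_var is None else prior_var, float),
        (d,)).copy()
    rng = rng if rng is not None else np.random.default_rng(0)

    def neg_fg(x):
        return problem.neg_log_post_grad(x, prior_mean, prior_var)

    starts = [prior_mean]
    if extra_starts is not None:
        starts += [np.asarray(s, float) for s in extra_starts]
    starts += [prior_mean + np.sqrt(prior_var) * rng.standard_normal(d)
               for _ in range(n_restarts)]

    best, converged = None, False
    for x0 in starts:
        res = minimize(neg_fg, x0, jac=True, method="L-BFGS-B")
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)
    if not converged:
        logger.warning("model %d subject %s: optimizer did not report "
                       "convergence after all restarts", model_id,
                       data.subject_id)
    lp = -float(best.fun)
    log_ev, cov, regularized = _laplace(problem, best.x, lp,
                                        lambda x: neg_fg(x)[1])
    return MAPFit(model_id, best.x, lp, log_ev, cov, converged, regularized)


# ---------------------------------------------------------------------------
# model-frequency calculus


def responsibilities(log_evidence, dirichlet_counts) -> np.ndarray:
    """Posterior probability that each subject's data came from each model:
    softmax over models of the log evidence plus the Dirichlet expected log
    frequency. Rows sum to 1."""
    L = np.atleast_2d(np.asarray(log_evidence, float))
    alpha = np.asarray(dirichlet_counts, float)
    logits = L + digamma(alpha) - digamma(alpha.sum())
    return np.exp(logits - logsumexp(logits, axis=1, keepdims=True))


def exceedance_probabilities(dirichlet_counts, n_draws: int = 10 ** 6,
                             rng: np.random.Generator | None = None
                             ) -> np.ndarray:
    """Monte Carlo probability that each model is the most frequent under a
    Dirichlet posterior over model frequencies."""
    alpha = np.asarray(dirichlet_counts, float)
    K = len(alpha)
    if K == 1:
        return np.ones(1)
    rng = rng if rng is not None else np.random.default_rng(0)
    wins = np.zeros(K)
    done = 0
    while done < n_draws:
        chunk = min(200_000, n_draws - done)
        samples = rng.dirichlet(alpha, size=chunk)
        wins += np.bincount(np.argmax(samples, axis=1), minlength=K)
        done += chunk
    return wins / n_draws


def protected_exceedance(dirichlet_counts, bor: float,
                         n_draws: int = 10 ** 6,
                         rng: np.random.Generator | None = None) -> np.ndarray:
    """pxp_k = xp_k * (1 - bor) + bor / K."""
    if not 0.0 <= bor <= 1.0:
        raise ValueError("bor must lie in [0, 1]")
    xp = exceedance_probabilities(dirichlet_counts, n_draws, rng)
    return xp * (1.0 - bor) + bor / len(xp)


def bayesian_omnibus_risk(log_evidence: np.ndarray, resp: np.ndarray,
                          alpha: np.ndarray, alpha0: float) -> float:
    """Probability that model frequencies are indistinguishable: compares the
    variational free energy of the fitted Dirichlet frequency model (F1)
    against the equal-frequency null (F0); bor = 1 / (1 + exp(F1 - F0))."""
    N, K = log_evidence.shape
    a = np.asarray(alpha, float)
    a0 = np.full(K, alpha0, float)
    elr = digamma(a) - digamma(a.sum())
    r = np.clip(resp, 1e-300, 1.0)
    f1 = float(np.sum(resp * (log_evidence + elr))
               - np.sum(resp * np.log(r)))
    kl = float(gammaln(a.sum()) - gammaln(a).sum()
               - gammaln(a0.sum()) + gammaln(a0).sum()
               + np.sum((a - a0) * (digamma(a) - digamma(a.sum()))))
    f1 -= kl
    f0 = float(np.sum(logsumexp(log_evidence - np.log(K), axis=1)))
    return float(1.0 / (1.0 + np.exp(np.clip(f1 - f0, -700, 700))))


def hbi_ttest(group_mean: float, hierarchical_error: float,
              dof: float) -> tuple[float, float]:
    """t statistic (group mean over hierarchical error) and two-sided p from
    a Student-t with method-supplied, possibly non-integer, dof."""
    if hierarchical_error <= 0:
        raise ValueError("hierarchical_error must be positive")
    t = group_mean / hierarchical_error
    p = 2.0 * float(student_t.sf(abs(t), dof))
    return float(t), p


# ---------------------------------------------------------------------------
# hierarchical fit


@dataclass
class GroupPosterior:
    """Group-level summary of one model after the hierarchical fit."""

    model_id: int
    parameter_names: tuple[str, ...]
    group_mean: np.ndarray        # raw space
    group_var: np.ndarray
    hierarchical_error: np.ndarray
    subject_map: np.ndarray       # subjects x params, raw space
    subject_var: np.ndarray
    model_frequency: float
    dirichlet_count: float
    dof: float

    def ttest(self, param: str) -> tuple[float, float]:
        i = self.parameter_names.index(param)
        return hbi_ttest(self.group_mean[i], self.hierarchical_error[i],
                         self.dof)


@dataclass
class ModelComparison:
    model_ids: tuple[int, ...]
    responsibilities: np.ndarray   # subjects x models
    model_frequency: np.ndarray
    dirichlet_counts: np.ndarray
    exceedance: np.ndarray
    pxp: np.ndarray
    bor: float


@dataclass
class HierarchicalFit:
    groups: dict[int, GroupPosterior]
    comparison: ModelComparison
    log_evidence: np.ndarray       # subjects x models
    converged: bool
    n_iterations: int

    def to_dict(self) -> dict:
        c = self.comparison
        return {
            "model_ids": list(c.model_ids),
            "responsibilities": c.responsibilities.tolist(),
            "model_frequency": c.model_frequency.tolist(),
            "dirichlet_counts": c.dirichlet_counts.tolist(),
            "exceedance": c.exceedance.tolist(),
            "pxp": c.pxp.tolist(),
            "bor": c.bor,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "groups": {
                str(k): {
                    "parameter_names": list(g.parameter_names),
                    "group_mean": g.group_mean.tolist(),
                    "group_var": g.group_var.tolist(),
                    "hierarchical_error": g.hierarchical_error.tolist(),
                    "subject_map": g.subject_map.tolist(),
                    "model_frequency": g.model_frequency,
                    "dof": g.dof,
                } for k, g in self.groups.items()
            },
        }


def fit_hierarchical(model_ids, subjects, *,
                     max_iterations: int = 50,
                     tol: float = 1e-4,
                     prior_mean: float = PRIOR_MEAN,
                     prior_var: float = PRIOR_VAR,
                     n_restarts: int = 4,
                     alpha0: float = 1.0,
                     variance_floor: float = 1e-6,
                     exceedance_draws: int = 10 ** 6,
                     rng: np.random.Generator | None = None,
                     seed: int | None = None) -> HierarchicalFit:
    """Hierarchical random-effects fit and comparison of several models.

    Iterates per-subject MAP fits under the current group priors,
    evidence-based responsibilities, and responsibility-weighted group
    updates, until the summed evidence changes by less than ``tol`` or
    ``max_iterations`` is reached (the result then carries a non-convergence
    flag). Per-subject fits are warm-started from the previous iteration's
    MAP; ``n_restarts`` prior draws are added in the first iteration only.
    """
    model_ids = [int(m) for m in model_ids]
    subjects = list(subjects)
    N, K = len(subjects), len(model_ids)
    if N < 2:
        raise ValueError("hierarchical fitting needs at least 2 subjects")
    if K < 1:
        raise ValueError("need at least one model")
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)

    problems = [[_SubjectModelProblem(m, s) for m in model_ids]
                for s in subjects]
    dims = [problems[0][k].d for k in range(K)]
    mu = [np.full(d, float(prior_mean)) for d in dims]
    var = [np.full(d, float(prior_var)) for d in dims]
    theta = [[None] * K for _ in range(N)]
    covd = [[None] * K for _ in range(N)]
    # cached likelihood part of the Hessian (the prior adds exactly
    # diag(1/prior_var)), reusable while the MAP stays put
    h_lik = [[None] * K for _ in range(N)]
    h_at = [[None] * K for _ in range(N)]
    L = np.zeros((N, K))
    alpha = np.full(K, float(alpha0))
    f_prev, converged, it = -np.inf, False, 0

    for it in range(1, max_iterations + 1):
        # E: subject-level MAP fits and Laplace evidences under group priors
        for n in range(N):
            for k in range(K):
                prob = problems[n][k]

                def neg_fg(x, prob=prob, k=k):
                    return prob.neg_log_post_grad(x, mu[k], var[k])

                # warm-start from the previous MAP; extra starts (the group
                # mean and prior draws) only in the first iterations, after
                # which the E-step is a deterministic refinement
                if theta[n][k] is None:
                    starts = [mu[k]]
                    starts += [mu[k] + np.sqrt(var[k])
                               * rng.standard_normal(dims[k])
                               for _ in range(n_restarts)]
                elif it <= 2:
                    starts = [theta[n][k], mu[k]]
                else:
                    starts = [theta[n][k]]
                best = None
                for x0 in starts:
                    res = minimize(neg_fg, x0, jac=True, method="L-BFGS-B")
                    if best is None or res.fun < best.fun:
                        best = res
                x = best.x
                if (h_lik[n][k] is not None
                        and float(np.max(np.abs(x - h_at[n][k]))) < 1e-6):
                    H = h_lik[n][k] + np.diag(1.0 / var[k])
                else:
                    H = _hessian_from_grad(lambda z: neg_fg(z)[1], x)
                    h_lik[n][k] = H - np.diag(1.0 / var[k])
                    h_at[n][k] = x.copy()
                w, V = np.linalg.eigh(H)
                if np.any(w <= 1e-10):
                    w = np.maximum(w, 1e-6)
                logdet = float(np.sum(np.log(w)))
                theta[n][k] = x
                covd[n][k] = np.einsum("ij,j,ij->i", V, 1.0 / w, V)
                L[n, k] = (-float(best.fun)
                           + 0.5 * dims[k] * np.log(2.0 * np.pi)
                           - 0.5 * logdet)

        resp = responsibilities(L, alpha)
        nk = resp.sum(axis=0)
        alpha = alpha0 + nk

        # M: responsibility-weighted group moments
        for k in range(K):
            th = np.array([theta[n][k] for n in range(N)])
            cd = np.array([covd[n][k] for n in range(N)])
            w = resp[:, k][:, None]
            denom = max(nk[k], 1e-12)
            mu[k] = (w * th).sum(axis=0) / denom
            var[k] = np.maximum(
                ((w * ((th - mu[k]) ** 2 + cd)).sum(axis=0)) / denom,
                variance_floor)

        f_total = float(np.sum(logsumexp(L + (digamma(alpha)
                                              - digamma(alpha.sum())),
                                         axis=1)))
        if abs(f_total - f_prev) < tol:
            converged = True
            break
        f_prev = f_total

    if not converged:
        logger.warning("hierarchical fit stopped at max_iterations=%d "
                       "without convergence", max_iterations)

    bor = bayesian_omnibus_risk(L, resp, alpha, alpha0)
    xp = exceedance_probabilities(alpha, exceedance_draws, rng)
    pxp = xp * (1.0 - bor) + bor / K
    freq = alpha / alpha.sum()

    groups = {}
    for k, m in enumerate(model_ids):
        nk_k = float(resp[:, k].sum())
        groups[m] = GroupPosterior(
            model_id=m,
            parameter_names=MODEL_SPECS[m].parameter_names,
            group_mean=mu[k].copy(),
            group_var=var[k].copy(),
            hierarchical_error=np.sqrt(var[k] / max(nk_k, 1e-12)),
            subject_map=np.array([theta[n][k] for n in range(N)]),
            subject_var=np.array([covd[n][k] for n in range(N)]),
            model_frequency=float(freq[k]),
            dirichlet_count=float(alpha[k]),
            dof=max(nk_k - 1.0, 1.0),
        )
    comparison = ModelComparison(tuple(model_ids), resp, freq, alpha.copy(),
                                 xp, pxp, float(bor))
    return HierarchicalFit(groups, comparison, L.copy(), converged, it)
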