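"""Marginal maximum-likelihood estimation of G-DINA family models by EM.

The latent structure is a finite mixture over the ``2**K`` attribute
mastery classes with saturated mixing proportions ``pi`` (``2**K - 1`` free
parameters).  Under local independence the likelihood of response vector
``X_i`` given class ``c`` is the product over items of
``P_j(c)**X_ij * (1 - P_j(c))**(1 - X_ij)``; the E-step turns these into
posterior class probabilities, the M-step re-estimates item probabilities
and ``pi``:

* G-DINA: each reduced-class success probability is set to (expected number
  correct) / (expected membership) within the reduced class — the closed-form
  maximizer of the expected complete-data log-likelihood — and is mapped to
  delta coefficients through the invertible identity-link system on demand.
* DINA / DINO: the same ratio after pooling reduced classes into the two
  groups the model distinguishes (all / at-least-one required attributes).
* RRUM: bounded numerical maximization of the expected complete-data
  log-likelihood over (pi*, r*) on a logit scale; the update is accepted
  only when it improves the objective, so the EM ascent property is kept
  (a generalized EM step).

The observed-data log-likelihood is therefore non-decreasing across
iterations for every model, which the test-suite asserts step by step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, logsumexp, logit

from .latent_space import LatentClassSpace, QMatrix, enumerate_patterns, reduced_class_map
from .models import MODELS, ItemResponseFunction, rrum_prob_vector

__all__ = [
    "EMConfig",
    "FitResult",
    "class_likelihoods",
    "class_log_likelihoods",
    "em_fit",
    "information_criteria",
    "item_parameter_count",
    "likelihood_ratio_test",
    "validate_responses",
]


def validate_responses(X) -> np.ndarray:
    """Coerce a response matrix to int8 and reject anything but complete 0/1."""
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError(f"response matrix must be 2-D with N>=1; got shape {X.shape}")
    if not np.isin(X, (0, 1)).all():
        bad = np.argwhere(~np.isin(X, (0, 1)))[0]
        raise ValueError(
            f"response at examinee {bad[0] + 1}, item {bad[1] + 1} is not 0/1 "
            f"(missing responses are not supported)"
        )
    return X.astype(np.int8)


@dataclass
class EMConfig:
    """Estimation settings.

    tol
        Convergence threshold on the max absolute change of any item
        probability or mixing proportion between iterations.  Reporting
        precision in diagnostic tables is two decimals, so 1e-4 is ample.
    clip
        Probabilities are kept in ``[clip, 1 - clip]`` during estimation to
        keep log-likelihoods finite; invisible at reporting precision.
    monotone
        If True, M-step G-DINA probability vectors are projected onto
        non-decreasing order in the number of mastered required attributes
        (pool-adjacent-violators with expected-membership weights).  Off by
        default: saturated fits may legitimately be non-monotone.
    """

    tol: float = 1e-4
    max_iter: int = 1000
    clip: float = 1e-4
    monotone: bool = False
    seed: int = 1  # reserved for randomized starts; the default start is deterministic


@dataclass
class FitResult:
    """EM output: item parameters, structural proportions, and diagnostics."""

    model: str
    irf: ItemResponseFunction
    pi: np.ndarray  # (2**K,) mixing proportions
    loglik: float
    n_params: int
    n_iter: int
    converged: bool
    max_change: float
    posterior: np.ndarray = field(repr=False)  # (N, 2**K)
    space: LatentClassSpace = field(repr=False, default=None)
    loglik_history: list = field(repr=False, default_factory=list)
    rrum_params: dict = field(repr=False, default_factory=dict)

    @property
    def N(self) -> int:
        return self.posterior.shape[0]

    @property
    def neg2ll(self) -> float:
        return -2.0 * self.loglik


def class_log_likelihoods(irf: ItemResponseFunction, X, space=None, clip=1e-10):
    """(N, 2**K) log-likelihood table log P(X_i | class c)."""
    X = validate_responses(X)
    if space is None:
        space = enumerate_patterns(irf.q.K)
    P = np.clip(irf.expand(space), clip, 1 - clip)
    logP = np.log(P)
    log1mP = np.log1p(-P)
    return X @ (logP - log1mP) + log1mP.sum(axis=0)[None, :]


def class_likelihoods(irf: ItemResponseFunction, X, space=None):
    """(N, 2**K) likelihood table — entry (i, c) is P(X_i | class c)."""
    return np.exp(class_log_likelihoods(irf, X, space))


def item_parameter_count(q: QMatrix, model: str) -> int:
    """Number of free item parameters for a model on a given Q-matrix."""
    kstar = q.item_attr_count
    if model == "gdina":
        return int((2 ** kstar).sum())
    if model in ("dina", "dino"):
        return 2 * q.J
    if model == "rrum":
        return int((1 + kstar).sum())
    raise ValueError(f"unknown model {model!r}")


def _default_init(q: QMatrix, model: str) -> list[np.ndarray]:
    """Deterministic start: probabilities spread 0.2 -> 0.8 along mastery count."""
    probs = []
    for j in range(q.J):
        kstar = int(q.item_attr_count[j])
        n = 1 << kstar
        r = np.arange(n)
        counts = np.array([bin(v).count("1") for v in r])
        order = np.lexsort((r, counts))
        p = np.empty(n)
        if model in ("dina",):
            p[:] = 0.2
            p[-1] = 0.8
        elif model == "dino":
            p[:] = 0.8
            p[0] = 0.2
        else:
            p[order] = np.linspace(0.2, 0.8, n)
        probs.append(p)
    return probs


def _pava_monotone(p: np.ndarray, w: np.ndarray, order: np.ndarray) -> np.ndarray:
    """Weighted pool-adjacent-violators along a given ordering of reduced classes."""
    blocks = [[p[i], w[i], 1] for i in order]  # [value, weight, size]
    i = 0
    while i < len(blocks) - 1:
        if blocks[i][0] > blocks[i + 1][0] + 1e-12:
            v0, w0, n0 = blocks[i]
            v1, w1, n1 = blocks[i + 1]
            blocks[i] = [(v0 * w0 + v1 * w1) / (w0 + w1), w0 + w1, n0 + n1]
            del blocks[i + 1]
            i = max(i - 1, 0)
        else:
            i += 1
    expanded = np.concatenate([np.full(n, v) for v, _, n in blocks])
    out = np.empty_like(p)
    out[order] = expanded
    return out


def _rrum_mstep(Nr, Rr, kstar, x0_logit):
    """Maximize the expected complete-data log-lik of one RRUM item.

    Parametrized as logits of (pi*, r*_1..r*_K*); returns the optimized
    (pi*, penalties) and the achieved objective.
    """
    r = np.arange(1 << kstar)[:, None]
    missing = 1 - ((r >> np.arange(kstar)) & 1)  # (2**k*, k*)

    def neg(x):
        pi_star = expit(x[0])
        pen = expit(x[1:])
        p = np.clip(pi_star * np.prod(pen[None, :] ** missing, axis=1), 1e-10, 1 - 1e-10)
        return -(Rr @ np.log(p) + (Nr - Rr) @ np.log1p(-p))

    res = optimize.minimize(neg, x0_logit, method="L-BFGS-B", options={"maxiter": 60})
    x = res.x if res.fun <= neg(x0_logit) else x0_logit
    return expit(x[0]), expit(x[1:]), -neg(x)


def em_fit(X, Q: QMatrix, model: str = "gdina", config: EMConfig | None = None,
           init: ItemResponseFunction | None = None, init_pi=None) -> FitResult:
    """Fit a cognitive diagnosis model by marginal maximum likelihood (EM).

    Parameters
    ----------
    X : (N, J) array of 0/1 responses.
    Q : QMatrix with matching J.
    model : one of ``gdina``, ``dina``, ``dino``, ``rrum``.
    init : optional ItemResponseFunction to start from (e.g. a previous fit).
    init_pi : optional starting mixing proportions (uniform by default).

    Returns a :class:`FitResult` whose ``posterior`` holds the (N, 2**K)
    posterior class probabilities of the final iteration.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    config = config or EMConfig()
    X = validate_responses(X)
    N, J = X.shape
    if J != Q.J:
        raise ValueError(f"responses have {J} items but Q-matrix has {Q.J} rows")
    space = enumerate_patterns(Q.K)
    C = space.n_classes
    if N < C:
        warnings.warn(
            f"N={N} examinees for {C} latent classes; structural proportions "
            f"will be weakly identified",
            stacklevel=2,
        )
    clip = config.clip
    maps = [reduced_class_map(Q.entries[j], space) for j in range(J)]
    kstar = Q.item_attr_count
    counts_by_item = [
        np.array([bin(v).count("1") for v in range(1 << int(k))]) for k in kstar
    ]

    if init is not None:
        probs = [np.clip(np.asarray(p, dtype=float), clip, 1 - clip) for p in init.probs]
    else:
        probs = _default_init(Q, model)
    if init_pi is not None:
        pi = np.asarray(init_pi, dtype=float).ravel()
        if pi.size != C or (pi < 0).any() or abs(pi.sum() - 1) > 1e-8:
            raise ValueError("init_pi must be a probability vector over the 2**K classes")
        pi = np.clip(pi, 1e-12, None)
        pi = pi / pi.sum()
    else:
        pi = np.full(C, 1.0 / C)
    rrum_pi = np.full(J, 0.8)
    rrum_pen = [np.full(int(k), 0.25 ** (1.0 / max(int(k), 1))) for k in kstar]
    if model == "rrum":
        if init is None:
            probs = [rrum_prob_vector(rrum_pi[j], rrum_pen[j]) for j in range(J)]
        else:  # read (pi*, r*) off the reduced-pattern vector of the start
            for j in range(J):
                n = 1 << int(kstar[j])
                rrum_pi[j] = probs[j][-1]
                rrum_pen[j] = np.array(
                    [probs[j][(n - 1) ^ (1 << t)] / max(probs[j][-1], 1e-12)
                     for t in range(int(kstar[j]))]
                )
                rrum_pen[j] = np.clip(rrum_pen[j], clip, 1.0)

    Xf = X.astype(np.float64)
    loglik_history: list[float] = []
    loglik = -np.inf
    max_change = np.inf
    n_iter = 0
    converged = False

    for n_iter in range(1, config.max_iter + 1):
        # E-step
        P = np.empty((J, C))
        for j in range(J):
            P[j] = probs[j][maps[j]]
        P = np.clip(P, clip, 1 - clip)
        logP = np.log(P)
        log1mP = np.log1p(-P)
        ll = Xf @ (logP - log1mP) + log1mP.sum(axis=0)[None, :] + np.log(pi)[None, :]
        lse = logsumexp(ll, axis=1)
        post = np.exp(ll - lse[:, None])
        loglik = float(lse.sum())
        loglik_history.append(loglik)

        # M-step
        Nc = post.sum(axis=0)  # (C,)
        Rjc = Xf.T @ post  # (J, C)
        new_pi = Nc / N
        new_probs = []
        for j in range(J):
            n = 1 << int(kstar[j])
            Nr = np.bincount(maps[j], weights=Nc, minlength=n)
            Rr = np.bincount(maps[j], weights=Rjc[j], minlength=n)
            if model == "gdina":
                with np.errstate(invalid="ignore", divide="ignore"):
                    p = np.where(Nr > 0, Rr / np.maximum(Nr, 1e-300), probs[j])
                if config.monotone:
                    counts = counts_by_item[j]
                    order = np.lexsort((np.arange(n), counts))
                    p = _pava_monotone(p, np.maximum(Nr, 1e-12), order)
            elif model in ("dina", "dino"):
                top = (slice(n - 1, n) if model == "dina" else slice(1, n))
                low = (slice(0, n - 1) if model == "dina" else slice(0, 1))
                g = Rr[low].sum() / max(Nr[low].sum(), 1e-300)
                h = Rr[top].sum() / max(Nr[top].sum(), 1e-300)
                p = np.empty(n)
                p[low] = g
                p[top] = h
            else:  # rrum
                x0 = np.concatenate(
                    ([logit(np.clip(rrum_pi[j], clip, 1 - clip))],
                     logit(np.clip(rrum_pen[j], clip, 1 - clip)))
                )
                rrum_pi[j], rrum_pen[j], _ = _rrum_mstep(Nr, Rr, int(kstar[j]), x0)
                p = rrum_prob_vector(rrum_pi[j], rrum_pen[j])
            new_probs.append(np.clip(p, clip, 1 - clip))

        max_change = max(
            max(float(np.abs(new_probs[j] - probs[j]).max()) for j in range(J)),
            float(np.abs(new_pi - pi).max()),
        )
        probs, pi = new_probs, new_pi
        if max_change < config.tol:
            converged = True
            break

    # final E-step quantities at the converged parameters
    P = np.empty((J, C))
    for j in range(J):
        P[j] = probs[j][maps[j]]
    P = np.clip(P, clip, 1 - clip)
    ll = Xf @ (np.log(P) - np.log1p(-P)) + np.log1p(-P).sum(axis=0)[None, :] + np.log(pi)[None, :]
    lse = logsumexp(ll, axis=1)
    post = np.exp(ll - lse[:, None])
    loglik = float(lse.sum())
    loglik_history.append(loglik)

    irf = ItemResponseFunction(model=model, q=Q, probs=[np.asarray(p) for p in probs])
    n_params = item_parameter_count(Q, model) + (C - 1)
    rrum_params = (
        {"pi_star": rrum_pi.copy(), "penalties": [p.copy() for p in rrum_pen]}
        if model == "rrum"
        else {}
    )
    return FitResult(
        model=model,
        irf=irf,
        pi=pi,
        loglik=loglik,
        n_params=n_params,
        n_iter=n_iter,
        converged=converged,
        max_change=max_change,
        posterior=post,
        space=space,
        loglik_history=loglik_history,
        rrum_params=rrum_params,
    )


def information_criteria(fit: FitResult, N: int | None = None):
    """(−2LL, AIC, BIC) with ``p`` = item parameters + 2**K − 1 proportions."""
    N = fit.N if N is None else N
    neg2ll = fit.neg2ll
    p = fit.n_params
    return neg2ll, neg2ll + 2 * p, neg2ll + p * np.log(N)


def likelihood_ratio_test(fit_full: FitResult, fit_nested: FitResult):
    """LR test of a constrained model (DINA/DINO/RRUM) against saturated G-DINA.

    Returns ``(LR, df, p)`` with ``LR = (−2LL_nested) − (−2LL_full)`` and a
    chi-square reference distribution on the parameter-count difference.
    """
    same_data = fit_full.N == fit_nested.N
    same_q = fit_full.irf.q == fit_nested.irf.q
    if not (same_data and same_q):
        raise ValueError("models must be fitted to the same responses and Q-matrix")
    if fit_full.model == fit_nested.model:
        pass  # self-comparison: LR 0, df 0
    elif not (fit_full.model == "gdina" and fit_nested.model in ("dina", "dino", "rrum")):
        raise ValueError(
            f"{fit_nested.model!r} is not nested in {fit_full.model!r}: only "
            f"DINA/DINO/RRUM within G-DINA (same Q, same data) are comparable"
        )
    lr = fit_nested.neg2ll - fit_full.neg2ll
    df = fit_full.n_params - fit_nested.n_params
    if df == 0:
        p = 1.0 if lr <= 1e-6 else 0.0
    else:
        p = float(stats.chi2.sf(max(lr, 0.0), df))
    return float(lr), int(df), p
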