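"""Examinee-level attribute inference and attribute association summaries.

From the posterior class probabilities of a fitted model we report three
classifiers per examinee:

* **EAP** — posterior-mean mastery probability per attribute,
  ``m_ik = sum_c P(c | X_i) * alpha_ck``;
* **MAP** — the most probable posterior pattern (ties broken towards the
  lowest class index, deterministically);
* **MLE** — the pattern maximizing the class likelihood, ignoring the
  structural prior.

Group-level summaries average EAP probabilities (optionally proportions of
MAP masters) over the whole cohort or over high/low scoring groups, and the
tetrachoric correlation matrix quantifies pairwise association between the
dichotomized attribute calls through an underlying bivariate normal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .latent_space import LatentClassSpace

__all__ = [
    "MasteryEstimate",
    "GroupProfile",
    "classify",
    "group_mastery",
    "plot_group_profiles",
    "tetrachoric",
    "tetrachoric_matrix",
]


@dataclass
class MasteryEstimate:
    """Per-examinee EAP mastery probabilities and MAP/MLE patterns."""

    eap: np.ndarray  # (N, K) posterior mastery probabilities
    map_index: np.ndarray  # (N,) class index of the posterior mode
    map_pattern: np.ndarray  # (N, K) binary
    mle_index: np.ndarray  # (N,)
    mle_pattern: np.ndarray  # (N, K) binary
    map_posterior: np.ndarray  # (N,) posterior mass at the MAP class
    n_ties: int = 0

    @property
    def N(self) -> int:
        return self.eap.shape[0]

    @property
    def K(self) -> int:
        return self.eap.shape[1]

    def map_strings(self) -> list[str]:
        return ["".join(str(int(b)) for b in row) for row in self.map_pattern]

    def to_frame(self, ids=None) -> pd.DataFrame:
        """Per-examinee table: EAP per attribute, MAP pattern, posterior max."""
        ids = np.arange(1, self.N + 1) if ids is None else np.asarray(ids)
        data = {"id": ids}
        for k in range(self.K):
            data[f"m_A{k + 1}"] = self.eap[:, k]
        data["map_pattern"] = self.map_strings()
        data["map_posterior"] = self.map_posterior
        return pd.DataFrame(data)


@dataclass
class GroupProfile:
    """Attribute-wise mean mastery for a group of examinees."""

    label: str
    mean_eap: np.ndarray  # (K,)
    share_map_master: np.ndarray  # (K,) proportion of MAP masters
    n: int


def classify(posterior: np.ndarray, space: LatentClassSpace,
             likelihood: np.ndarray | None = None) -> MasteryEstimate:
    """Turn posterior (and optionally likelihood) tables into mastery estimates.

    ``argmax`` ties resolve to the lowest class index; the number of tied
    rows is recorded on the result.
    """
    posterior = np.asarray(posterior, dtype=float)
    if posterior.ndim != 2 or posterior.shape[1] != space.n_classes:
        raise ValueError(
            f"posterior shape {posterior.shape} does not match {space.n_classes} classes"
        )
    patterns = space.patterns.astype(float)
    eap = posterior @ patterns
    map_index = posterior.argmax(axis=1)
    ties = int((np.isclose(posterior, posterior.max(axis=1, keepdims=True)).sum(axis=1) > 1).sum())
    if likelihood is None:
        mle_index = map_index.copy()
    else:
        likelihood = np.asarray(likelihood, dtype=float)
        if likelihood.shape != posterior.shape:
            raise ValueError("likelihood table must have the same shape as the posterior")
        mle_index = likelihood.argmax(axis=1)
    return MasteryEstimate(
        eap=eap,
        map_index=map_index,
        map_pattern=space.patterns[map_index].astype(np.int8),
        mle_index=mle_index,
        mle_pattern=space.patterns[mle_index].astype(np.int8),
        map_posterior=posterior[np.arange(posterior.shape[0]), map_index],
        n_ties=ties,
    )


def group_mastery(estimates: MasteryEstimate, total_scores=None,
                  quantile: float = 0.5) -> dict[str, GroupProfile]:
    """Cohort-level mastery profiles, optionally split into high/low scorers.

    The split point is the ``quantile`` of raw total scores (median by
    default); examinees at or above it form the high group.  The split rule
    is a package convention — callers studying ability groups should treat
    it as a configurable choice, not an estimate.
    """
    if estimates.N < 1:
        raise ValueError("no examinees to profile")

    def profile(label, mask):
        n = int(mask.sum())
        if n == 0:
            raise ValueError(f"group {label!r} is empty")
        return GroupProfile(
            label=label,
            mean_eap=estimates.eap[mask].mean(axis=0),
            share_map_master=estimates.map_pattern[mask].mean(axis=0),
            n=n,
        )

    out = {"all": profile("all", np.ones(estimates.N, dtype=bool))}
    if total_scores is not None:
        scores = np.asarray(total_scores, dtype=float).ravel()
        if scores.size != estimates.N:
            raise ValueError("one total score per examinee expected")
        cut = np.quantile(scores, quantile)
        out["high"] = profile("high", scores >= cut)
        out["low"] = profile("low", scores < cut)
    return out


def plot_group_profiles(profiles: dict[str, GroupProfile], attr_names=None,
                        use="mean_eap", path=None):
    """Bar chart of attribute mastery per group (requires matplotlib).

    ``use`` selects EAP means (default) or the share of MAP masters.
    Returns the matplotlib Axes; saves to ``path`` when given.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    labels = list(profiles)
    K = profiles[labels[0]].mean_eap.size
    attr_names = attr_names or [f"A{k + 1}" for k in range(K)]
    x = np.arange(K)
    width = 0.8 / len(labels)
    fig, ax = plt.subplots(figsize=(1.2 * K + 2, 4))
    for i, label in enumerate(labels):
        vals = getattr(profiles[label], use)
        ax.bar(x + i * width, vals, width, label=f"{label} (n={profiles[label].n})")
    ax.set_xticks(x + width * (len(labels) - 1) / 2)
    ax.set_xticklabels(attr_names)
    ax.set_ylabel("mean mastery probability" if use == "mean_eap" else "share of MAP masters")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return ax


def tetrachoric(x, y, correction: float = 0.5):
    """Tetrachoric correlation of two binary vectors.

    Thresholds are fixed at the normal quantiles of the margins and the
    latent correlation solves ``Phi2(t_x, t_y; rho) = P(x=0, y=0)`` — the
    maximum-likelihood estimate under the bivariate-normal model with
    margin-matched thresholds.  A zero cell triggers a ``+correction`` to
    all four cells (flagged via a warning).

    Returns ``nan`` when either column is constant (undefined).
    """
    x = np.asarray(x).ravel()
    y = np.asarray(y).ravel()
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    n00 = float(np.sum((x == 0) & (y == 0)))
    n01 = float(np.sum((x == 0) & (y == 1)))
    n10 = float(np.sum((x == 1) & (y == 0)))
    n11 = float(np.sum((x == 1) & (y == 1)))
    if (n00 + n01 == 0) or (n10 + n11 == 0) or (n00 + n10 == 0) or (n01 + n11 == 0):
        return float("nan")
    if min(n00, n01, n10, n11) == 0:
        warnings.warn("zero cell in 2x2 table: continuity correction applied", stacklevel=2)
        n00 += correction
        n01 += correction
        n10 += correction
        n11 += correction
    n = n00 + n01 + n10 + n11
    tx = stats.norm.ppf((n00 + n01) / n)  # P(x = 0)
    ty = stats.norm.ppf((n00 + n10) / n)
    target = n00 / n

    def f(rho):
        cov = np.array([[1.0, rho], [rho, 1.0]])
        return stats.multivariate_normal.cdf([tx, ty], mean=[0.0, 0.0], cov=cov) - target

    lo, hi = -0.9999, 0.9999
    flo, fhi = f(lo), f(hi)
    if flo > 0:
        return -1.0
    if fhi < 0:
        return 1.0
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


def tetrachoric_matrix(calls) -> np.ndarray:
    """K x K tetrachoric correlation matrix of binary attribute calls.

    Diagonal 1; entries are ``nan`` where a column is constant (the
    correlation is undefined there and reported as missing).
    """
    calls = np.asarray(calls)
    if calls.ndim != 2:
        raise ValueError("expected an N x K matrix of binary calls")
    K = calls.shape[1]
    R = np.eye(K)
    for a in range(K):
        for b in range(a + 1, K):
            R[a, b] = R[b, a] = tetrachoric(calls[:, a], calls[:, b])
    return R
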