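"""Classification accuracy and reliability indices.

For a fitted model the expected agreement between the MAP classification
and the (unknown) true pattern can be estimated from the posterior itself:

* test level — average posterior mass at each examinee's MAP pattern,
  ``(1/N) sum_i P(alpha = MAP_i | X_i)``;
* attribute level — per attribute ``k``, the average posterior probability
  that the MAP call for that attribute is correct,
  ``(1/N) sum_i P(alpha_k = MAP_ik | X_i)``;
* pattern level — the test-level average restricted to the examinees whose
  MAP equals a given pattern (undefined for patterns nobody is assigned
  to; low-support patterns with few examinees are flagged because their
  accuracy estimates are unstable).

Cohen's kappa summarizes chance-corrected agreement between two binary
classifications.  When a simulated truth is available kappa compares MAP
calls to it ("truth" mode); otherwise the report carries the
posterior-expected self-consistency ("posterior" mode), i.e. the same
attribute-level agreement chance-corrected against the marginal call
rates.  The mode is always recorded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classification import MasteryEstimate
from .latent_space import LatentClassSpace

__all__ = [
    "AccuracyReport",
    "classification_accuracy",
    "kappa",
    "kappa_by_attribute",
    "pattern_prevalence",
]

LOW_SUPPORT = 30  # pattern cells below this count are flagged as unstable


def kappa(a, b) -> float:
    """Cohen's kappa of two binary classifications.

    ``kappa = (p_o - p_e) / (1 - p_e)`` from the 2x2 agreement table.  When
    both vectors are constant and equal, chance agreement ``p_e`` is 1 and
    kappa is undefined; 1.0 is returned (the classifications agree
    perfectly, if trivially).
    """
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.size != b.size:
        raise ValueError("classifications must have equal length")
    if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
        raise ValueError("classifications must be binary")
    p_o = float((a == b).mean())
    pa, pb = a.mean(), b.mean()
    p_e = pa * pb + (1 - pa) * (1 - pb)
    if p_e >= 1.0 - 1e-12:
        return 1.0 if p_o >= 1.0 - 1e-12 else 0.0
    return (p_o - p_e) / (1 - p_e)


def kappa_by_attribute(calls_a, calls_b) -> np.ndarray:
    """Per-attribute Cohen's kappa between two N x K call matrices."""
    calls_a = np.asarray(calls_a)
    calls_b = np.asarray(calls_b)
    if calls_a.shape != calls_b.shape:
        raise ValueError("call matrices must have the same shape")
    return np.array([kappa(calls_a[:, k], calls_b[:, k]) for k in range(calls_a.shape[1])])


@dataclass
class AccuracyReport:
    test_level: float
    attribute_level: np.ndarray  # (K,)
    pattern_level: pd.DataFrame  # pattern, n, share, accuracy, low_support
    kappa: np.ndarray  # (K,)
    kappa_mode: str  # "truth" or "posterior"
    prevalence: pd.DataFrame

    @property
    def attribute_mean(self) -> float:
        return float(np.mean(self.attribute_level))


def pattern_prevalence(estimates: MasteryEstimate) -> pd.DataFrame:
    """Share of examinees per MAP pattern, sorted by share (descending)."""
    strings = estimates.map_strings()
    counts = pd.Series(strings).value_counts()
    df = pd.DataFrame(
        {"pattern": counts.index, "n": counts.to_numpy(),
         "share": counts.to_numpy() / estimates.N}
    )
    return df.reset_index(drop=True)


def classification_accuracy(posterior, estimates: MasteryEstimate,
                            space: LatentClassSpace,
                            truth=None) -> AccuracyReport:
    """Three-level classification accuracy plus kappa summaries.

    ``truth`` — optional N x K matrix of true mastery patterns (simulation
    studies); switches kappa to truth mode.
    """
    posterior = np.asarray(posterior, dtype=float)
    N = posterior.shape[0]
    if N != estimates.N:
        raise ValueError("posterior and estimates cover different examinees")

    post_at_map = posterior[np.arange(N), estimates.map_index]
    test_level = float(post_at_map.mean())

    # P(alpha_k = MAP_ik | X_i) = m_ik if called mastered else 1 - m_ik
    agree = np.where(estimates.map_pattern == 1, estimates.eap, 1 - estimates.eap)
    attribute_level = agree.mean(axis=0)

    strings = np.array(estimates.map_strings())
    rows = []
    for pat in pd.unique(strings):
        mask = strings == pat
        rows.append(
            {
                "pattern": pat,
                "n": int(mask.sum()),
                "share": float(mask.mean()),
                "accuracy": float(post_at_map[mask].mean()),
                "low_support": bool(mask.sum() < LOW_SUPPORT),
            }
        )
    pattern_level = (
        pd.DataFrame(rows).sort_values("share", ascending=False).reset_index(drop=True)
    )

    if truth is not None:
        truth = np.asarray(truth)
        if truth.shape != estimates.map_pattern.shape:
            raise ValueError("truth matrix must be N x K")
        kap = kappa_by_attribute(estimates.map_pattern, truth)
        mode = "truth"
    else:
        # chance-corrected posterior self-consistency per attribute
        kap = np.empty(space.K)
        for k in range(space.K):
            p_o = attribute_level[k]
            call_rate = estimates.map_pattern[:, k].mean()
            eap_rate = estimates.eap[:, k].mean()
            p_e = call_rate * eap_rate + (1 - call_rate) * (1 - eap_rate)
            kap[k] = 1.0 if p_e >= 1 - 1e-12 else (p_o - p_e) / (1 - p_e)
        mode = "posterior"

    return AccuracyReport(
        test_level=test_level,
        attribute_level=attribute_level,
        pattern_level=pattern_level,
        kappa=kap,
        kappa_mode=mode,
        prevalence=pattern_prevalence(estimates),
    )
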