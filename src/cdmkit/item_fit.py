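"""Absolute item-fit statistics for a fitted cognitive diagnosis model.

Three residual statistics compare the observed response distribution with
the one the fitted mixture implies:

* ``l_jj'`` — absolute difference of observed and model-implied log odds
  ratios of an item pair, with ``OR = n11 * n00 / (n10 * n01)``;
* ``r_jj'`` — absolute difference of Fisher-z transformed observed and
  model-implied Pearson correlations of an item pair;
* ``p_j`` — absolute difference of observed and model-implied proportion
  correct of a single item.

Model-implied ("predicted") moments are computed analytically from the
fitted class proportions and item response functions — e.g.
``E[X_j X_j'] = sum_c pi_c P_j(c) P_j'(c)`` — rather than by simulating
prediction data; the expectation is identical and free of Monte-Carlo
noise.

Each statistic gets an asymptotic z-test (SE of the observed log OR from
the inverse cell counts, SE of a Fisher z from ``1/sqrt(N-3)``, binomial SE
for a proportion), with Bonferroni correction over all ``J(J-1)/2`` pairs
(or ``J`` items for ``p``) at a configurable level.  The summary mirrors
the conventional report: mean, max, and the SE at the pair/item achieving
the max ("SEmax").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import FitResult, validate_responses

__all__ = [
    "predicted_moments",
    "observed_pair_tables",
    "log_odds_itemfit",
    "transformed_correlation_itemfit",
    "proportion_correct_itemfit",
    "fisher_z",
    "itemfit_report",
    "ItemFitReport",
]

_CLAMP = 1.0 - 1e-6


def fisher_z(r: float) -> float:
    """Fisher transform with correlations clamped to ``|r| <= 1 - 1e-6``."""
    r = float(np.clip(r, -_CLAMP, _CLAMP))
    return float(np.arctanh(r))


def predicted_moments(fit: FitResult) -> dict:
    """Model-implied item means, pairwise cell probabilities and correlations."""
    P = fit.irf.expand(fit.space)  # (J, C)
    pi = fit.pi
    means = P @ pi
    E11 = (P * pi) @ P.T  # E[X_j X_j']
    p11 = E11
    p10 = means[:, None] - E11
    p01 = means[None, :] - E11
    p00 = 1.0 - p11 - p10 - p01
    denom = np.sqrt(np.clip(means * (1 - means), 1e-300, None))
    corr = (E11 - np.outer(means, means)) / np.outer(denom, denom)
    return {"means": means, "p11": p11, "p10": p10, "p01": p01, "p00": p00, "corr": corr}


def observed_pair_tables(X) -> dict:
    """Observed item means, pairwise 2x2 cell counts and correlations."""
    X = validate_responses(X).astype(float)
    N = X.shape[0]
    n11 = X.T @ X
    n10 = X.T @ (1 - X)
    n01 = (1 - X).T @ X
    n00 = (1 - X).T @ (1 - X)
    means = X.mean(axis=0)
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.where(np.isfinite(corr), corr, 0.0)
    return {"N": N, "means": means, "n11": n11, "n10": n10, "n01": n01, "n00": n00,
            "corr": corr, "sd": sd}


def _log_or(n11, n10, n01, n00, correction=0.5):
    cells = np.array([n11, n10, n01, n00], dtype=float)
    corrected = False
    if (cells <= 0).any():
        cells = cells + correction
        corrected = True
    lo = float(np.log(cells[0] * cells[3] / (cells[1] * cells[2])))
    se = float(np.sqrt((1.0 / cells).sum()))
    return lo, se, corrected


def log_odds_itemfit(observed_cells, predicted_cells) -> float:
    """``l = |log OR_observed - log OR_predicted|`` for one item pair.

    Both arguments are ``(n11, n10, n01, n00)`` tuples (counts or expected
    counts); zero cells get a +0.5 continuity correction.
    """
    lo_obs, _, _ = _log_or(*observed_cells)
    lo_pred, _, _ = _log_or(*predicted_cells)
    return abs(lo_obs - lo_pred)


def transformed_correlation_itemfit(corr_observed: float, corr_predicted: float) -> float:
    """``r = |Z(corr_observed) - Z(corr_predicted)|`` (Fisher-transformed)."""
    return abs(fisher_z(corr_observed) - fisher_z(corr_predicted))


def proportion_correct_itemfit(mean_observed: float, mean_predicted: float) -> float:
    """``p = |observed proportion correct - model-implied proportion correct|``."""
    return abs(float(mean_observed) - float(mean_predicted))


@dataclass
class ItemFitReport:
    pairs: pd.DataFrame  # long format: one row per item pair (l and r statistics)
    items: pd.DataFrame  # one row per item (p statistic)
    summary: pd.DataFrame  # mean / max / SEmax per statistic
    alpha: float
    bonferroni: bool


def itemfit_report(fit: FitResult, X, alpha: float = 0.1, bonferroni: bool = True) -> ItemFitReport:
    """All three item-fit statistics with z-tests and multiplicity control."""
    X = validate_responses(X)
    obs = observed_pair_tables(X)
    pred = predicted_moments(fit)
    N = obs["N"]
    J = X.shape[1]
    n_pairs = J * (J - 1) // 2
    level_pair = alpha / n_pairs if (bonferroni and n_pairs) else alpha
    level_item = alpha / J if bonferroni else alpha
    from scipy.stats import norm

    rows = []
    for j in range(J):
        for jp in range(j + 1, J):
            lo_obs, se_l, corrected = _log_or(
                obs["n11"][j, jp], obs["n10"][j, jp], obs["n01"][j, jp], obs["n00"][j, jp]
            )
            lo_pred, _, _ = _log_or(
                N * pred["p11"][j, jp], N * pred["p10"][j, jp],
                N * pred["p01"][j, jp], N * pred["p00"][j, jp]
            )
            l_stat = abs(lo_obs - lo_pred)
            r_stat = transformed_correlation_itemfit(obs["corr"][j, jp], pred["corr"][j, jp])
            se_r = 1.0 / np.sqrt(max(N - 3, 1))
            z_l = l_stat / se_l if se_l > 0 else np.inf
            z_r = r_stat / se_r
            rows.append(
                {
                    "item_a": j + 1,
                    "item_b": jp + 1,
                    "l": l_stat,
                    "se_l": se_l,
                    "p_l": 2 * norm.sf(z_l),
                    "sig_l": 2 * norm.sf(z_l) < level_pair,
                    "r": r_stat,
                    "se_r": se_r,
                    "p_r": 2 * norm.sf(z_r),
                    "sig_r": 2 * norm.sf(z_r) < level_pair,
                    "continuity_corrected": corrected,
                }
            )
    pairs = pd.DataFrame(rows)

    item_rows = []
    for j in range(J):
        p_stat = proportion_correct_itemfit(obs["means"][j], pred["means"][j])
        se_p = float(np.sqrt(max(obs["means"][j] * (1 - obs["means"][j]), 1e-300) / N))
        z = p_stat / se_p if se_p > 0 else np.inf
        item_rows.append(
            {
                "item": j + 1,
                "p": p_stat,
                "se_p": se_p,
                "p_value": 2 * norm.sf(z),
                "sig_p": 2 * norm.sf(z) < level_item,
            }
        )
    items = pd.DataFrame(item_rows)

    def summarize(values, ses):
        i = int(np.argmax(values))
        return {"mean": float(np.mean(values)), "max": float(values[i]), "se_max": float(ses[i])}

    summary = pd.DataFrame(
        {
            "l": summarize(pairs["l"].to_numpy(), pairs["se_l"].to_numpy()),
            "r": summarize(pairs["r"].to_numpy(), pairs["se_r"].to_numpy()),
            "p": summarize(items["p"].to_numpy(), items["se_p"].to_numpy()),
        }
    ).T[["mean", "max", "se_max"]]
    return ItemFitReport(pairs=pairs, items=items, summary=summary,
                         alpha=alpha, bonferroni=bonferroni)
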