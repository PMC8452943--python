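"""Q-matrix validation (discrimination index / PVAF) and DFL discretization.

Validation rule
---------------
For each item a saturated success-probability vector over the full ``2**K``
latent classes is obtained from one G-DINA fit of the provisional Q-matrix
(the E-step expected-correct / expected-membership ratios with the item
treated as requiring all attributes).  For every candidate q-vector the
discrimination index

``zeta2(q) = sum_g w_g (Pbar_g - Pbar)**2``

is the pi-weighted between-group variance of the success probabilities
after collapsing classes into the groups the candidate distinguishes
(``w_g`` the group pi-mass, ``Pbar`` the overall pi-weighted mean).  The
proportion of variance accounted for, ``PVAF(q) = zeta2(q) / zeta2(ones)``,
is 1 for the full vector by construction.  The selected q-vector is the one
with the fewest required attributes reaching the PVAF cutoff (0.95 by
default), ties broken by larger PVAF and then lexicographically.

The revised matrix is advisory: the per-item tables and change log are
returned alongside it so that domain judgement can override the statistics.

DFL discretization
------------------
A continuous factor-loading matrix becomes a binary Q-matrix by the
row-average rule: ``q_jk = 1`` iff ``|lambda_jk|`` is at least the mean of
the absolute loadings in row ``j``.  Absolute values are used because the
sign of a loading is rotation-dependent; ties pass the threshold, so the
row maximum always survives and every row keeps at least one attribute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import EMConfig, FitResult, em_fit, validate_responses
from .latent_space import LatentClassSpace, QMatrix, enumerate_patterns, reduced_class_map

__all__ = [
    "zeta2",
    "pvaf_table",
    "validate_qmatrix",
    "dfl_discretize",
    "QValidationResult",
]


def zeta2(q_candidate, class_probs, success_probs, space: LatentClassSpace | None = None) -> float:
    """Discrimination index of a candidate q-vector.

    Parameters
    ----------
    q_candidate : length-K binary vector (at least one 1).
    class_probs : pi over the 2**K classes (simplex).
    success_probs : item success probability per full class.
    """
    pi = np.asarray(class_probs, dtype=float).ravel()
    P = np.asarray(success_probs, dtype=float).ravel()
    if pi.size != P.size:
        raise ValueError("class_probs and success_probs must cover the same classes")
    K = int(pi.size).bit_length() - 1
    if pi.size != 1 << K:
        raise ValueError(f"{pi.size} classes is not a power of two")
    if space is None:
        space = enumerate_patterns(K)
    rmap = reduced_class_map(q_candidate, space)
    n_groups = int(rmap.max()) + 1
    w = np.bincount(rmap, weights=pi, minlength=n_groups)
    wp = np.bincount(rmap, weights=pi * P, minlength=n_groups)
    with np.errstate(invalid="ignore", divide="ignore"):
        group_mean = np.where(w > 0, wp / np.maximum(w, 1e-300), 0.0)
    overall = float(pi @ P) / max(float(pi.sum()), 1e-300)
    return float(np.sum(w * (group_mean - overall) ** 2))


def _zeta2_and_penalty(q_candidate, pi, P, space, n_obs):
    """Raw between-group variance and its expected sampling-noise content.

    Each group mean is estimated from roughly ``N * w_g`` effective
    observations, so its sampling variance ``Pbar_g (1 - Pbar_g) / (N w_g)``
    contributes ``Pbar_g (1 - Pbar_g) / N`` of pure noise to the weighted
    between-group variance.  Subtracting this expectation debiases the
    index; without it the fully saturated (all-attribute) vector absorbs
    the noise of every class and the PVAF of the true q-vector is pushed
    below any high cutoff as the class space grows.
    """
    rmap = reduced_class_map(q_candidate, space)
    n_groups = int(rmap.max()) + 1
    w = np.bincount(rmap, weights=pi, minlength=n_groups)
    wp = np.bincount(rmap, weights=pi * P, minlength=n_groups)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(w > 0, wp / np.maximum(w, 1e-300), 0.0)
    overall = float(pi @ P)
    z = float(np.sum(w * (mean - overall) ** 2))
    penalty = 0.0
    if n_obs:
        penalty = float(np.sum((w > 0) * mean * (1 - mean)) / n_obs)
    return z, penalty


def pvaf_table(class_probs, success_probs, space: LatentClassSpace,
               n_obs: int | None = None) -> pd.DataFrame:
    """zeta2 and PVAF of every non-zero candidate q-vector for one item.

    When ``n_obs`` (the sample size behind the success-probability
    estimates) is given, PVAF uses noise-debiased variances; estimates from
    exact population quantities (``n_obs=None``) use the raw ratio.
    """
    pi = np.asarray(class_probs, dtype=float).ravel()
    P = np.asarray(success_probs, dtype=float).ravel()
    full = np.ones(space.K, dtype=np.int8)
    z_full, pen_full = _zeta2_and_penalty(full, pi, P, space, n_obs)
    adj_full = max(z_full - pen_full, 0.0)
    rows = []
    for c in range(1, space.n_classes):
        cand = space.patterns[c]
        z, pen = _zeta2_and_penalty(cand, pi, P, space, n_obs)
        adj = max(z - pen, 0.0)
        if adj_full > 0:
            pvaf = min(adj / adj_full, 1.0)
        else:
            pvaf = 1.0 if c == space.n_classes - 1 else 0.0
        rows.append(
            {
                "q_vector": "".join(str(int(b)) for b in cand),
                "n_attributes": int(cand.sum()),
                "zeta2": z,
                "pvaf": pvaf,
            }
        )
    return pd.DataFrame(rows)


def _select_qvector(table: pd.DataFrame, cutoff: float) -> str:
    ok = table[table["pvaf"] >= cutoff]
    if ok.empty:  # fall back to the full vector (always PVAF 1 up to rounding)
        ok = table[table["n_attributes"] == table["n_attributes"].max()]
    best_size = ok["n_attributes"].min()
    ok = ok[ok["n_attributes"] == best_size]
    ok = ok.sort_values(["pvaf", "q_vector"], ascending=[False, True], kind="mergesort")
    return str(ok.iloc[0]["q_vector"])


@dataclass
class QValidationResult:
    q_revised: QMatrix
    tables: list  # per-item PVAF DataFrames
    changes: pd.DataFrame  # items whose q-vector changed
    fit: FitResult

    @property
    def n_changed(self) -> int:
        return len(self.changes)


def validate_qmatrix(X, Q_initial: QMatrix, cutoff: float = 0.95,
                     fit: FitResult | None = None,
                     config: EMConfig | None = None) -> QValidationResult:
    """Validate and revise a Q-matrix by the PVAF stepwise rule.

    A saturated G-DINA fit of ``(X, Q_initial)`` supplies the structural
    proportions and posteriors; each item's saturated success probabilities
    over the full class space are the posterior-expected correct rates.  The
    revised matrix replaces each item's q-vector with the minimal one whose
    PVAF reaches ``cutoff``.
    """
    X = validate_responses(X)
    if fit is None:
        fit = em_fit(X, Q_initial, model="gdina", config=config)
    space = fit.space
    post = fit.posterior
    Nc = post.sum(axis=0)
    Rjc = X.astype(float).T @ post
    with np.errstate(invalid="ignore", divide="ignore"):
        P_full = np.where(Nc > 0, Rjc / np.maximum(Nc, 1e-300), 0.5)  # (J, 2**K)
    pi = fit.pi

    tables = []
    new_rows = []
    change_rows = []
    for j in range(Q_initial.J):
        table = pvaf_table(pi, P_full[j], space, n_obs=X.shape[0])
        tables.append(table)
        selected = _select_qvector(table, cutoff)
        new_row = np.array([int(b) for b in selected], dtype=np.int8)
        old = "".join(str(int(b)) for b in Q_initial.entries[j])
        new_rows.append(new_row)
        if selected != old:
            change_rows.append(
                {
                    "item": j + 1,
                    "old_q": old,
                    "new_q": selected,
                    "pvaf_old": float(
                        table.set_index("q_vector").loc[old, "pvaf"]
                    ),
                    "pvaf_new": float(
                        table.set_index("q_vector").loc[selected, "pvaf"]
                    ),
                }
            )
    q_revised = QMatrix(entries=np.vstack(new_rows), attr_names=Q_initial.attr_names)
    changes = pd.DataFrame(change_rows, columns=["item", "old_q", "new_q", "pvaf_old", "pvaf_new"])
    return QValidationResult(q_revised=q_revised, tables=tables, changes=changes, fit=fit)


def dfl_discretize(loadings, attr_names=()) -> QMatrix:
    """Discretize a factor-loading matrix into a Q-matrix (row-average rule)."""
    L = np.asarray(loadings, dtype=float)
    if L.ndim != 2:
        raise ValueError("loading matrix must be 2-D")
    if not np.isfinite(L).all():
        raise ValueError("loadings must be finite")
    A = np.abs(L)
    zero = np.flatnonzero(A.sum(axis=1) == 0)
    if zero.size:
        raise ValueError(
            f"rows {[int(j) + 1 for j in zero]} are identically zero: no signal to discretize"
        )
    thresh = A.mean(axis=1, keepdims=True)
    return QMatrix(entries=(A >= thresh).astype(np.int8), attr_names=tuple(attr_names))
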