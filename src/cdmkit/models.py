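"""Item response functions for the G-DINA family.

Every model here gives, for item ``j``, the probability of a correct answer
as a function of the *reduced* mastery pattern — the projection of the full
pattern onto the ``K*_j`` attributes the item requires.

* **G-DINA** (saturated, identity link): the success probability is an
  intercept plus main effects and all interaction effects of the required
  attributes,

  ``P(alpha*) = d_0 + sum_k d_k a_k + sum_{k<k'} d_kk' a_k a_k' + ... + d_{1..K*} prod_k a_k``.

  With ``2**K*`` coefficients the map between delta coefficients and the
  vector of reduced-pattern probabilities is an invertible linear system.
* **DINA** (conjunctive): ``1 - s`` when *all* required attributes are
  mastered, else ``g``.
* **DINO** (disjunctive): ``1 - s`` when *at least one* required attribute is
  mastered, else ``g``.
* **RRUM** (reduced reparametrized unified model): baseline ``pi*`` for full
  mastery, multiplied by a penalty ``r*_k`` for every required attribute not
  mastered.

No monotonicity in the number of mastered attributes is imposed on G-DINA:
saturated fits to real data routinely produce non-monotone probability
vectors and boundary values (0 or 1), and both are accepted.  An optional
isotone projection is available at estimation time.

Reduced patterns are indexed like the full space: reduced class ``r`` has
its ``t``-th required attribute mastered iff bit ``t`` of ``r`` is set.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations

import numpy as np

from .latent_space import LatentClassSpace, QMatrix, reduced_class_map

__all__ = [
    "MODELS",
    "interaction_subsets",
    "gdina_design_matrix",
    "gdina_probability",
    "gdina_prob_vector",
    "delta_from_probabilities",
    "dina_probability",
    "dino_probability",
    "rrum_probability",
    "rrum_prob_vector",
    "ItemResponseFunction",
]

MODELS = ("gdina", "dina", "dino", "rrum")


@lru_cache(maxsize=None)
def interaction_subsets(k_star: int) -> tuple[tuple[int, ...], ...]:
    """Delta-coefficient ordering: intercept, main effects, then interactions.

    Subsets of the required-attribute positions ``0..K*-1`` ordered by size
    then lexicographically; the empty subset is the intercept.
    """
    subs: list[tuple[int, ...]] = [()]
    for size in range(1, k_star + 1):
        subs.extend(combinations(range(k_star), size))
    return tuple(subs)


@lru_cache(maxsize=None)
def gdina_design_matrix(k_star: int) -> np.ndarray:
    """(2**K*, 2**K*) matrix M with ``probs = M @ delta``.

    Row ``r`` is the reduced pattern with bits of ``r``; column ``t`` is the
    subset ``interaction_subsets(k_star)[t]``; the entry is 1 iff the subset
    is contained in the mastered set of the pattern.
    """
    subs = interaction_subsets(k_star)
    n = 1 << k_star
    M = np.zeros((n, n))
    for r in range(n):
        mastered = {t for t in range(k_star) if (r >> t) & 1}
        for col, sub in enumerate(subs):
            M[r, col] = 1.0 if set(sub) <= mastered else 0.0
    M.setflags(write=False)
    return M


def _reduced_index(reduced) -> tuple[int, int]:
    reduced = np.asarray(reduced).ravel()
    if not np.isin(reduced, (0, 1)).all():
        raise ValueError("reduced pattern entries must be 0 or 1")
    k = reduced.size
    r = int(reduced.astype(np.int64) @ (1 << np.arange(k, dtype=np.int64)))
    return r, k


def gdina_prob_vector(delta: np.ndarray) -> np.ndarray:
    """All reduced-pattern success probabilities implied by a delta vector."""
    delta = np.asarray(delta, dtype=float).ravel()
    n = delta.size
    k_star = int(n).bit_length() - 1
    if n != 1 << k_star or n < 1:
        raise ValueError(f"delta length {n} is not a power of two")
    probs = gdina_design_matrix(k_star) @ delta
    if (probs < -1e-9).any() or (probs > 1 + 1e-9).any():
        raise ValueError(
            f"delta parameters imply probabilities outside [0, 1]: {np.round(probs, 6)}"
        )
    return np.clip(probs, 0.0, 1.0)


def gdina_probability(delta, reduced) -> float:
    """Saturated (identity-link) success probability at one reduced pattern."""
    r, k = _reduced_index(reduced)
    probs = gdina_prob_vector(delta)
    if probs.size != 1 << k:
        raise ValueError(
            f"delta has {probs.size} coefficients but reduced pattern has {k} attributes"
        )
    return float(probs[r])


def delta_from_probabilities(probs) -> np.ndarray:
    """Invert the identity-link map: reduced-pattern probabilities -> delta.

    The linear system is square and invertible, so the delta vector is the
    unique one reproducing ``probs`` exactly.
    """
    probs = np.asarray(probs, dtype=float).ravel()
    n = probs.size
    k_star = int(n).bit_length() - 1
    if n != 1 << k_star or n < 2:
        raise ValueError(f"probability vector length {n} is not a power of two >= 2")
    if (probs < 0).any() or (probs > 1).any():
        raise ValueError("probabilities must lie in [0, 1]")
    return np.linalg.solve(gdina_design_matrix(k_star), probs)


def _check_gs(g: float, s: float) -> None:
    if not (0 <= g <= 1 and 0 <= s <= 1):
        raise ValueError(f"guess/slip must lie in [0, 1]; got g={g}, s={s}")
    if g >= 1 - s:
        warnings.warn(
            f"guessing g={g} >= 1-slipping {1 - s}: item discriminates in reverse",
            stacklevel=3,
        )


def dina_probability(g: float, s: float, reduced) -> float:
    """Conjunctive model: 1-s iff all required attributes mastered, else g."""
    _check_gs(g, s)
    reduced = np.asarray(reduced).ravel()
    return float(1 - s) if reduced.all() else float(g)


def dino_probability(g: float, s: float, reduced) -> float:
    """Disjunctive model: 1-s iff at least one required attribute mastered, else g."""
    _check_gs(g, s)
    reduced = np.asarray(reduced).ravel()
    return float(1 - s) if reduced.any() else float(g)


def rrum_probability(pi_star: float, penalties, reduced) -> float:
    """RRUM: baseline ``pi*`` with one penalty factor per missing attribute."""
    penalties = np.asarray(penalties, dtype=float).ravel()
    reduced = np.asarray(reduced).ravel()
    if reduced.size != penalties.size:
        raise ValueError("one penalty per required attribute expected")
    if not 0 <= pi_star <= 1:
        raise ValueError(f"baseline pi*={pi_star} outside [0, 1]")
    if (penalties < 0).any() or (penalties > 1).any():
        raise ValueError("penalties r* must lie in [0, 1]")
    if (penalties == 0).any():
        warnings.warn("penalty r*=0 makes non-mastery probability exactly 0", stacklevel=2)
    return float(pi_star * np.prod(penalties ** (1 - reduced)))


def rrum_prob_vector(pi_star: float, penalties) -> np.ndarray:
    """All reduced-pattern probabilities of an RRUM item."""
    penalties = np.asarray(penalties, dtype=float).ravel()
    k = penalties.size
    r = np.arange(1 << k)[:, None]
    missing = 1 - ((r >> np.arange(k)) & 1)
    return pi_star * np.prod(penalties[None, :] ** missing, axis=1)


@dataclass
class ItemResponseFunction:
    """Per-item success probabilities over reduced patterns.

    ``probs[j]`` has length ``2**K*_j`` in reduced-pattern order.  This is the
    common currency of the package: every model's fitted (or generating)
    parameters are stored this way, with named parameters recoverable
    (``guess``/``slip`` read off the endpoints, ``item_delta`` through the
    inverse linear map).
    """

    model: str
    q: QMatrix
    probs: list = field(repr=False)

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODELS}")
        if len(self.probs) != self.q.J:
            raise ValueError(f"{len(self.probs)} probability vectors for J={self.q.J} items")
        clean = []
        for j, p in enumerate(self.probs):
            p = np.asarray(p, dtype=float).ravel()
            expected = 1 << int(self.q.item_attr_count[j])
            if p.size != expected:
                raise ValueError(
                    f"item {j + 1}: {p.size} probabilities, expected {expected}"
                )
            if (p < 0).any() or (p > 1).any():
                raise ValueError(f"item {j + 1}: probabilities outside [0, 1]")
            clean.append(p)
        self.probs = clean

    @property
    def guess(self) -> np.ndarray:
        """P(correct | no required attribute mastered) per item."""
        return np.array([p[0] for p in self.probs])

    @property
    def slip(self) -> np.ndarray:
        """1 - P(correct | all required attributes mastered) per item."""
        return np.array([1 - p[-1] for p in self.probs])

    def item_delta(self, j: int) -> np.ndarray:
        """Delta coefficients of item ``j`` under the saturated identity link."""
        return delta_from_probabilities(self.probs[j])

    def expand(self, space: LatentClassSpace) -> np.ndarray:
        """(J, 2**K) matrix of success probabilities over the full class space."""
        if space.K != self.q.K:
            raise ValueError(f"space has K={space.K}, Q-matrix has K={self.q.K}")
        P = np.empty((self.q.J, space.n_classes))
        for j in range(self.q.J):
            P[j] = self.probs[j][reduced_class_map(self.q.entries[j], space)]
        return P

    # --- constructors -----------------------------------------------------

    @classmethod
    def from_guess_slip(cls, q: QMatrix, guess, slip, model: str = "dina"):
        if model not in ("dina", "dino"):
            raise ValueError("guess/slip parametrization applies to dina or dino")
        guess = np.broadcast_to(np.asarray(guess, dtype=float), (q.J,))
        slip = np.broadcast_to(np.asarray(slip, dtype=float), (q.J,))
        probs = []
        for j in range(q.J):
            n = 1 << int(q.item_attr_count[j])
            p = np.full(n, guess[j])
            if model == "dina":
                p[-1] = 1 - slip[j]
            else:
                p[1:] = 1 - slip[j]
            probs.append(p)
        return cls(model=model, q=q, probs=probs)

    @classmethod
    def from_rrum(cls, q: QMatrix, pi_star, penalties):
        pi_star = np.broadcast_to(np.asarray(pi_star, dtype=float), (q.J,))
        probs = [rrum_prob_vector(pi_star[j], penalties[j]) for j in range(q.J)]
        return cls(model="rrum", q=q, probs=probs)

    @classmethod
    def from_delta(cls, q: QMatrix, deltas):
        return cls(model="gdina", q=q, probs=[gdina_prob_vector(d) for d in deltas])

    # --- serialization ----------------------------------------------------

    def to_json(self, path=None) -> str:
        items = []
        for j in range(self.q.J):
            items.append(
                {
                    "item": j + 1,
                    "required_attributes": [int(k) + 1 for k in self.q.required(j)],
                    "probs": [float(p) for p in self.probs[j]],
                }
            )
        payload = json.dumps(
            {"model": self.model, "q": self.q.entries.tolist(), "items": items}, indent=1
        )
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, source):
        if isinstance(source, (str, bytes)) and not str(source).lstrip().startswith("{"):
            with open(source, "r", encoding="utf-8") as fh:
                data = json.load(fh)
        elif isinstance(source, (str, bytes)):
            data = json.loads(source)
        else:
            data = json.load(source)
        q = QMatrix(entries=np.asarray(data["q"]))
        probs = [np.asarray(item["probs"], dtype=float) for item in data["items"]]
        return cls(model=data["model"], q=q, probs=probs)
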