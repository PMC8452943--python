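"""Attribute patterns, latent-class spaces, and the Q-matrix.

Cognitive diagnosis models describe an examinee by a length-``K`` binary
mastery pattern ``alpha``: entry ``k`` is 1 when attribute ``k`` is mastered.
With ``K`` attributes there are ``2**K`` distinct patterns (latent classes).

Canonical class ordering
------------------------
Class index ``c`` encodes the pattern whose ``k``-th attribute (0-based) is
bit ``k`` of ``c`` — attribute 1 is the fastest-varying bit.  For ``K = 2``
the order is ``(0,0), (1,0), (0,1), (1,1)``.  Every module in the package
(EM posteriors, discrimination indices, simulation truth) uses this indexing,
and serialized outputs inherit it.

Items and attributes are 1-based in user-facing I/O ("A1".."AK", item 1..J)
and 0-based internally; the reader/writer functions are the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AttributePattern",
    "LatentClassSpace",
    "QMatrix",
    "enumerate_patterns",
    "reduce_pattern",
    "reduced_class_map",
    "read_qmatrix",
    "write_qmatrix",
]

#: Hard ceiling on the attribute count; 2**20 classes is already far past any
#: practical diagnostic design and guards against combinatorial blow-up.
MAX_ATTRIBUTES = 20

AttributePattern = np.ndarray  # length-K vector of {0,1} mastery indicators


@dataclass(frozen=True)
class LatentClassSpace:
    """All ``2**K`` attribute mastery patterns in canonical order."""

    K: int
    patterns: np.ndarray = field(repr=False)  # (2**K, K) int8

    @property
    def n_classes(self) -> int:
        return 1 << self.K

    def index_of(self, pattern) -> int:
        """Canonical class index of a mastery pattern (inverse of ``patterns[c]``)."""
        bits = np.asarray(pattern, dtype=np.int64).ravel()
        if bits.size != self.K:
            raise ValueError(f"pattern has length {bits.size}, expected K={self.K}")
        if not np.isin(bits, (0, 1)).all():
            raise ValueError("pattern entries must be 0 or 1")
        return int(bits @ (1 << np.arange(self.K, dtype=np.int64)))

    def pattern_string(self, c: int) -> str:
        """Render class ``c`` as an attribute string like ``'0011100'``."""
        return "".join(str(int(b)) for b in self.patterns[c])

    def __len__(self) -> int:
        return self.n_classes


def enumerate_patterns(K: int) -> LatentClassSpace:
    """Enumerate all ``2**K`` mastery patterns in canonical order.

    Parameters
    ----------
    K : int
        Number of attributes, ``1 <= K <= 20``.
    """
    if not isinstance(K, (int, np.integer)) or isinstance(K, bool):
        raise TypeError(f"K must be an integer, got {type(K).__name__}")
    if not 1 <= K <= MAX_ATTRIBUTES:
        raise ValueError(
            f"attribute count K={K} outside supported range 1..{MAX_ATTRIBUTES} "
            f"(2**K latent classes would be intractable)"
        )
    c = np.arange(1 << K, dtype=np.int64)[:, None]
    patterns = ((c >> np.arange(K)) & 1).astype(np.int8)
    patterns.setflags(write=False)
    return LatentClassSpace(K=int(K), patterns=patterns)


@dataclass(frozen=True)
class QMatrix:
    """J x K binary item-attribute incidence matrix.

    ``entries[j, k] == 1`` means item ``j`` requires attribute ``k``.  Every
    item must require at least one attribute.
    """

    entries: np.ndarray  # (J, K) int8
    attr_names: tuple[str, ...] = ()

    def __post_init__(self):
        entries = np.asarray(self.entries)
        if entries.ndim != 2 or entries.shape[0] < 1 or entries.shape[1] < 1:
            raise ValueError(f"Q-matrix must be 2-D with J>=1, K>=1; got shape {entries.shape}")
        if not np.isin(entries, (0, 1)).all():
            bad = np.argwhere(~np.isin(entries, (0, 1)))[0]
            raise ValueError(
                f"Q-matrix entry at item {bad[0] + 1}, attribute {bad[1] + 1} is not 0/1"
            )
        zero = np.flatnonzero(entries.sum(axis=1) == 0)
        if zero.size:
            raise ValueError(
                f"Q-matrix items {[int(j) + 1 for j in zero]} require no attribute "
                f"(all-zero rows are invalid)"
            )
        entries = entries.astype(np.int8)
        entries.setflags(write=False)
        object.__setattr__(self, "entries", entries)
        names = tuple(self.attr_names) or tuple(f"A{k + 1}" for k in range(entries.shape[1]))
        if len(names) != entries.shape[1]:
            raise ValueError(f"{len(names)} attribute names for K={entries.shape[1]} attributes")
        object.__setattr__(self, "attr_names", names)

    @property
    def J(self) -> int:
        return self.entries.shape[0]

    @property
    def K(self) -> int:
        return self.entries.shape[1]

    @property
    def item_attr_count(self) -> np.ndarray:
        """K*_j — number of attributes each item requires."""
        return self.entries.sum(axis=1).astype(int)

    def required(self, j: int) -> np.ndarray:
        """0-based indices of the attributes item ``j`` requires."""
        return np.flatnonzero(self.entries[j])

    def __eq__(self, other) -> bool:
        return isinstance(other, QMatrix) and np.array_equal(self.entries, other.entries)

    def __hash__(self):
        return hash(self.entries.tobytes())


def reduce_pattern(q_row, alpha) -> np.ndarray:
    """Project a full mastery pattern onto the attributes an item requires.

    Returns the sub-vector of ``alpha`` at positions where ``q_row == 1``,
    preserving attribute order.  Item response functions depend on ``alpha``
    only through this reduced pattern.
    """
    q_row = np.asarray(q_row)
    alpha = np.asarray(alpha)
    if q_row.shape != alpha.shape:
        raise ValueError(f"q_row shape {q_row.shape} != pattern shape {alpha.shape}")
    req = np.flatnonzero(q_row)
    if req.size == 0:
        raise ValueError("item requires no attribute (all-zero q-vector)")
    return alpha[req]


def reduced_class_map(q_row, space: LatentClassSpace) -> np.ndarray:
    """Map every full class index to the item's reduced class index.

    For an item requiring ``K*`` attributes the reduced classes are indexed
    ``0 .. 2**K* - 1`` with the first required attribute as the fastest bit
    (same convention as the full space).  Each reduced class receives exactly
    ``2**(K - K*)`` full classes.
    """
    q_row = np.asarray(q_row).ravel()
    if q_row.size != space.K:
        raise ValueError(f"q_row length {q_row.size} != K={space.K}")
    req = np.flatnonzero(q_row)
    if req.size == 0:
        raise ValueError("item requires no attribute (all-zero q-vector)")
    bits = space.patterns[:, req].astype(np.int64)
    return bits @ (1 << np.arange(req.size, dtype=np.int64))


def _looks_like_header(first_line: str) -> bool:
    for tok in first_line.strip().split(","):
        tok = tok.strip()
        if tok == "":
            continue
        try:
            float(tok)
            return False
        except ValueError:
            return True
    return False


def read_qmatrix(path) -> QMatrix:
    """Read a Q-matrix from CSV (0/1 cells, optional header of attribute names)."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        first = fh.readline()
    header = 0 if _looks_like_header(first) else None
    df = pd.read_csv(path, header=header)
    values = df.to_numpy()
    # locate non-binary cells with 1-based coordinates for the error message
    numeric = pd.DataFrame(values).apply(pd.to_numeric, errors="coerce").to_numpy()
    bad = np.argwhere(~np.isin(numeric, (0.0, 1.0)) | np.isnan(numeric))
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"{path.name}: cell at row {r + 1}, column {c + 1} is not 0/1 "
            f"(value {values[r, c]!r})"
        )
    names = tuple(str(c) for c in df.columns) if header == 0 else ()
    return QMatrix(entries=numeric.astype(np.int8), attr_names=names)


def write_qmatrix(q: QMatrix, path) -> None:
    """Write a Q-matrix to CSV with its attribute-name header."""
    df = pd.DataFrame(q.entries, columns=list(q.attr_names))
    df.to_csv(path, index=False)
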