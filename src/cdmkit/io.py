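"""CSV / JSON readers and writers for responses and fit results.

Formats: comma-separated UTF-8 with "." decimals.  Response CSVs are N rows
by J columns of 0/1 with an optional header and an optional examinee-id
first column (detected when the first column is not strictly 0/1).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .estimation import FitResult, information_criteria
from .latent_space import QMatrix
from .models import ItemResponseFunction

__all__ = ["read_responses", "write_responses", "fit_to_json", "fit_from_json", "file_sha256"]


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def read_responses(path):
    """Read a response matrix CSV; returns ``(X, ids)`` with ids possibly None."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        first = fh.readline()
    tokens = [t.strip() for t in first.strip().split(",")]

    def _numeric(tok):
        try:
            float(tok)
            return True
        except ValueError:
            return False

    header = 0 if any(not _numeric(t) for t in tokens if t != "") else None
    df = pd.read_csv(path, header=header)
    ids = None
    first_col = df.iloc[:, 0]
    numeric_first = pd.to_numeric(first_col, errors="coerce")
    if numeric_first.isna().any() or not numeric_first.isin([0, 1]).all():
        ids = first_col.to_numpy()
        df = df.iloc[:, 1:]
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy()
    bad = np.argwhere(~np.isin(values, (0.0, 1.0)) | np.isnan(values))
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"{path.name}: response at row {r + 1}, column {c + 1} is not 0/1"
        )
    return values.astype(np.int8), ids


def write_responses(X, path, ids=None) -> None:
    X = np.asarray(X)
    df = pd.DataFrame(X, columns=[f"item{j + 1}" for j in range(X.shape[1])])
    if ids is not None:
        df.insert(0, "id", np.asarray(ids))
    df.to_csv(path, index=False)


def fit_to_json(fit: FitResult, path=None, q_path=None) -> str:
    """Serialize a fit: model, Q hash, fit indices, item parameters, pi."""
    neg2ll, aic, bic = information_criteria(fit)
    payload = {
        "model": fit.model,
        "q_sha256": hashlib.sha256(fit.irf.q.entries.tobytes()).hexdigest(),
        "q": fit.irf.q.entries.tolist(),
        "q_path": str(q_path) if q_path else None,
        "N": fit.N,
        "neg2ll": neg2ll,
        "aic": aic,
        "bic": bic,
        "n_params": fit.n_params,
        "n_iter": fit.n_iter,
        "converged": fit.converged,
        "max_change": fit.max_change,
        "items": [
            {
                "item": j + 1,
                "required_attributes": [int(k) + 1 for k in fit.irf.q.required(j)],
                "probs": [float(p) for p in fit.irf.probs[j]],
            }
            for j in range(fit.irf.q.J)
        ],
        "pi": [float(p) for p in fit.pi],
    }
    text = json.dumps(payload, indent=1)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def fit_from_json(path) -> dict:
    """Load a serialized fit; item parameters return as an ItemResponseFunction."""
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    q = QMatrix(entries=np.asarray(data["q"]))
    data["irf"] = ItemResponseFunction(
        model=data["model"], q=q,
        probs=[np.asarray(it["probs"], dtype=float) for it in data["items"]],
    )
    data["pi"] = np.asarray(data["pi"], dtype=float)
    return data
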