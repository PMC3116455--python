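"""Plain-text serialisation for semantic matrices, kernels and models.

Matrices travel as a JSON header line followed by sparse triplets
(``row<TAB>col<TAB>value``); fitted models as a single JSON document.
Everything round-trips losslessly at float64 repr precision.
"""

from __future__ import annotations

import json

import numpy as np
import scipy.sparse as sp

from .pmkl import PMKLModel


def save_matrix(path: str, matrix, header: dict | None = None) -> None:
    """Write a dense or sparse matrix as JSON header + triplet lines."""
    if sp.issparse(matrix):
        coo = matrix.tocoo()
        shape = coo.shape
        rows, cols, vals = coo.row, coo.col, coo.data
    else:
        arr = np.asarray(matrix, dtype=np.float64)
        shape = arr.shape
        rows, cols = np.nonzero(arr)
        vals = arr[rows, cols]
    meta = dict(header or {})
    meta["shape"] = list(shape)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(json.dumps(meta) + "\n")
        for r, c, v in zip(rows, cols, vals):
            fh.write(f"{int(r)}\t{int(c)}\t{float(v)!r}\n")


def load_matrix(path: str, sparse: bool = False):
    """Read a triplet file back; returns (matrix, header)."""
    with open(path, encoding="utf-8") as fh:
        meta = json.loads(fh.readline())
        shape = tuple(meta["shape"])
        rows, cols, vals = [], [], []
        for line in fh:
            r, c, v = line.rstrip("\n").split("\t")
            rows.append(int(r))
            cols.append(int(c))
            vals.append(float(v))
    if sparse:
        return (
            sp.coo_matrix((vals, (rows, cols)), shape=shape).tocsr(),
            meta,
        )
    arr = np.zeros(shape)
    arr[rows, cols] = vals
    return arr, meta


def model_to_json(model: PMKLModel) -> str:
    """Serialise a fitted model (posterior summary, not factorisations)."""
    payload = {
        "beta": model.beta.tolist(),
        "mu": model.mu.tolist(),
        "classes": model.classes.tolist(),
        "mode": model.mode,
        "convergence_trace": model.convergence_trace,
        "seed": model.seed,
        "n_kernels": model.n_kernels,
    }
    if model._sigma_d is not None:
        payload["sigma_U"] = model._sigma_U.tolist()
        payload["sigma_d"] = model._sigma_d.tolist()
    else:
        payload["sigma"] = model._sigma.tolist()
    return json.dumps(payload)


def model_from_json(doc: str) -> PMKLModel:
    payload = json.loads(doc)
    return PMKLModel(
        beta=np.asarray(payload["beta"]),
        mu=np.asarray(payload["mu"]),
        classes=np.asarray(payload["classes"]),
        mode=payload["mode"],
        convergence_trace=list(payload["convergence_trace"]),
        seed=payload["seed"],
        n_kernels=payload["n_kernels"],
        _sigma_U=np.asarray(payload["sigma_U"]) if "sigma_U" in payload else None,
        _sigma_d=np.asarray(payload["sigma_d"]) if "sigma_d" in payload else None,
        _sigma=np.asarray(payload["sigma"]) if "sigma" in payload else None,
    )
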