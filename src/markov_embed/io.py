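"""Reading and writing matrices and reports.

Matrix files: CSV/TSV (d rows of d separated floats, no header) or JSON
``{"matrix": [[...]]}`` with an optional ``"exact"`` field of rational
strings like ``"3/10"``, which enables exact-arithmetic classification of
the Jordan pattern (numerics are still used for the logarithms).
"""

from __future__ import annotations

import json
from fractions import Fraction
from pathlib import Path
from typing import Optional

import numpy as np

from .matrix_core import MarkovMatrix, RateMatrix, validate_markov, validate_rate

__all__ = ["read_matrix", "read_exact", "write_report", "exact_classification"]


def _load_array(path: Path, fmt: Optional[str]) -> np.ndarray:
    if fmt is None:
        fmt = {".csv": "csv", ".tsv": "tsv", ".json": "json"}.get(path.suffix.lower())
    if fmt == "csv":
        return np.loadtxt(path, delimiter=",", ndmin=2)
    if fmt == "tsv":
        return np.loadtxt(path, delimiter="\t", ndmin=2)
    if fmt == "json":
        data = json.loads(path.read_text())
        if "exact" in data and "matrix" not in data:
            return np.array([[float(Fraction(v)) for v in row] for row in data["exact"]])
        return np.asarray(data["matrix"], dtype=float)
    raise ValueError(f"unknown matrix format for {path}")


def read_matrix(path, fmt: Optional[str] = None, kind: str = "markov",
                tol: float = 1.0e-9) -> MarkovMatrix | RateMatrix:
    """Read and validate a matrix file as a Markov matrix or generator."""
    arr = _load_array(Path(path), fmt)
    if kind == "markov":
        return validate_markov(arr, tol)
    if kind == "rate":
        return validate_rate(arr, tol)
    raise ValueError("kind must be 'markov' or 'rate'")


def read_exact(path) -> Optional[list[list[Fraction]]]:
    """Return the exact rational entries of a JSON matrix file, if present."""
    p = Path(path)
    if p.suffix.lower() != ".json":
        return None
    data = json.loads(p.read_text())
    if "exact" not in data:
        return None
    return [[Fraction(v) for v in row] for row in data["exact"]]


def exact_classification(entries: list[list[Fraction]]) -> Optional[dict]:
    """Exact-arithmetic Jordan classification of a rational matrix.

    Returns algebraic/geometric multiplicities and the minimal-polynomial
    degree computed without floating point, removing clustering ambiguity
    for printed examples.  Falls back to ``None`` when the symbolic
    computation does not terminate cleanly.
    """
    try:
        import sympy as sp

        M = sp.Matrix([[sp.Rational(f.numerator, f.denominator) for f in row]
                       for row in entries])
        d = M.shape[0]
        ev = M.eigenvals()
        clusters = []
        deg = 0
        for val, alg in ev.items():
            geo = d - (M - val * sp.eye(d)).rank()
            max_block = alg - geo + 1
            deg += max_block
            clusters.append({"value": complex(val.evalf()), "alg": int(alg),
                             "geo": int(geo), "max_block": int(max_block)})
        return {"minpoly_degree": int(deg), "clusters": clusters}
    except Exception:
        return None


def write_report(result, path) -> None:
    """Serialise an EmbeddingResult / GEmbedReport / dict to JSON."""
    obj = result.to_dict() if hasattr(result, "to_dict") else result
    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")


def _default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serialisable: {type(o)}")
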