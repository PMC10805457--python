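"""Reading feature matrices and covariances; serializing test results.

Inputs are generic delimited numeric tables (e.g. log-normalized expression
matrices), rows = observations, columns = features.  Results serialize to a
flat JSON record; cluster labels are written 1-based, matching the usual
"cluster 1 vs cluster 2" reporting convention, and converted back on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import IntervalUnion
from .inference import TestResult

__all__ = ["read_matrix", "read_covariance", "result_to_dict", "result_from_dict",
           "write_result", "read_result"]


def _sniff_delimiter(path: Path, delimiter):
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_matrix(path, delimiter=None, header: bool = False, index_col: bool = False):
    """Read an n x q numeric matrix from a delimited text file.

    Returns ``(values, row_ids)``; ``row_ids`` is None unless ``index_col``
    is set, in which case the first column is kept as observation labels.
    Non-numeric cells and ragged rows raise a parse error naming the
    location.
    """
    path = Path(path)
    delimiter = _sniff_delimiter(path, delimiter)
    try:
        df = pd.read_csv(
            path,
            sep=delimiter,
            header=0 if header else None,
            index_col=0 if index_col else None,
        )
    except pd.errors.ParserError as e:
        raise ValueError(f"{path}: malformed table: {e}") from None
    converted = df.apply(pd.to_numeric, errors="coerce")
    bad = (converted.isna() & df.notna()).to_numpy()
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: non-numeric value {df.iat[i, j]!r} at row {i + 1}, column {j + 1}"
        )
    values = converted.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(f"{path}: non-finite value at row {i + 1}, column {j + 1}")
    row_ids = list(df.index) if index_col else None
    return values, row_ids


def read_covariance(path, delimiter=None, tol: float = 1e-8) -> np.ndarray:
    """Read a q x q covariance matrix; enforce symmetry to ``tol``, then
    symmetrize."""
    values, _ = read_matrix(path, delimiter=delimiter)
    if values.shape[0] != values.shape[1]:
        raise ValueError(f"{path}: covariance must be square, got {values.shape}")
    if not np.allclose(values, values.T, atol=tol * max(1.0, np.abs(values).max())):
        raise ValueError(f"{path}: covariance matrix is not symmetric")
    return (values + values.T) / 2.0


def result_to_dict(result: TestResult) -> dict:
    """Flat JSON-ready record; pair labels are 1-based on disk."""
    return {
        "stat": result.stat,
        "p_selective": result.p_selective,
        "p_naive": result.p_naive,
        "region": result.region.to_json_obj(),
        "sigma": result.sigma,
        "sigma_source": result.sigma_source,
        "pair": [result.pair[0] + 1, result.pair[1] + 1],
        "K": result.K,
        "T": result.T,
        "converged": result.converged,
        "n": result.n,
        "q": result.q,
        "seed": result.seed,
    }


def result_from_dict(obj: dict) -> TestResult:
    return TestResult(
        stat=obj["stat"],
        p_selective=obj["p_selective"],
        p_naive=obj["p_naive"],
        region=IntervalUnion.from_json_obj(obj["region"]),
        sigma=obj["sigma"],
        sigma_source=obj["sigma_source"],
        pair=(obj["pair"][0] - 1, obj["pair"][1] - 1),
        K=obj["K"],
        T=obj["T"],
        converged=obj["converged"],
        n=obj["n"],
        q=obj["q"],
        seed=obj["seed"],
    )


def write_result(result: TestResult, path) -> None:
    Path(path).write_text(json.dumps(result_to_dict(result), indent=2) + "\n")


def read_result(path) -> TestResult:
    return result_from_dict(json.loads(Path(path).read_text()))
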