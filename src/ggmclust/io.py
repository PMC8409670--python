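"""Readers and writers for the delimited-text and JSON artifacts.

Input is delimited text (comma by default, tab accepted) with a header
row of variable names and one row per subject. Outputs are diff-able
text: model summaries as JSON, labels and tables as CSV, networks as TSV
edge lists or full CSV matrices.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import DataMatrix, WeightedNetwork
from .exceptions import FailureRecord, MissingDataError, ParseError


def read_data(
    path: str | Path,
    delimiter: str = ",",
    group_column: str | None = None,
) -> tuple[DataMatrix, pd.Series | None]:
    """Read a subjects-by-variables table; returns (DataMatrix, groups).

    Missing cells raise :class:`MissingDataError` naming every offending
    (row, column); non-numeric cells raise :class:`ParseError` likewise.
    Column order is preserved. ``group_column``, if given, is split off as
    a categorical grouping vector (e.g., diagnostic labels).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, dtype=str, skipinitialspace=True)
    if df.empty or df.shape[1] == 0:
        raise ParseError(f"{path}: no parseable data")
    groups = None
    if group_column is not None:
        if group_column not in df.columns:
            raise ParseError(f"{path}: no column named {group_column!r}")
        groups = df.pop(group_column).rename(group_column)

    missing: list[tuple[int, str]] = []
    bad: list[tuple[int, str]] = []
    values = np.empty(df.shape, dtype=float)
    for c, col in enumerate(df.columns):
        raw = df[col]
        blank = raw.isna() | (raw.str.strip() == "")
        coerced = pd.to_numeric(raw, errors="coerce")
        missing.extend((int(r) + 2, col) for r in np.flatnonzero(blank))  # +2: header + 1-based
        bad.extend(
            (int(r) + 2, col)
            for r in np.flatnonzero(coerced.isna().to_numpy() & ~blank.to_numpy())
        )
        values[:, c] = coerced.to_numpy()
    if missing:
        where = ", ".join(f"(line {r}, column {c})" for r, c in missing[:10])
        raise MissingDataError(f"{path}: missing cells at {where}")
    if bad:
        where = ", ".join(f"(line {r}, column {c})" for r, c in bad[:10])
        raise ParseError(f"{path}: non-numeric cells at {where}")
    return DataMatrix(values, list(df.columns)), groups


def write_data(data: DataMatrix, path: str | Path, delimiter: str = ",") -> None:
    data.to_dataframe().to_csv(path, sep=delimiter, index=False, float_format="%.17g")


def read_community_map(path: str | Path) -> dict[str, str]:
    """Two-column (variable, community) file, tab- or comma-delimited."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: need two columns (variable, community)")
    first = df.iloc[0]
    if str(first[0]).lower() in ("variable", "node", "name"):
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0].str.strip(), df.iloc[:, 1].str.strip()))


def write_community_map(communities: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("variable\tcommunity\n")
        for var, com in communities.items():
            fh.write(f"{var}\t{com}\n")


def write_labels(labels: np.ndarray, path: str | Path) -> None:
    """Labels CSV with 1-based cluster numbers for human consumption."""
    pd.DataFrame(
        {"subject_index": np.arange(1, len(labels) + 1), "cluster": np.asarray(labels) + 1}
    ).to_csv(path, index=False)


def read_labels(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    return df["cluster"].to_numpy(dtype=int) - 1


def write_network_edges(net: WeightedNetwork, path: str | Path) -> None:
    net.edge_dataframe().to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_network_matrix(net: WeightedNetwork, path: str | Path) -> None:
    net.to_dataframe().to_csv(path, float_format="%.10g")


def read_network_matrix(path: str | Path, scale: str = "covariance") -> WeightedNetwork:
    df = pd.read_csv(path, index_col=0)
    return WeightedNetwork(df.to_numpy(dtype=float), list(df.columns), scale=scale)


def read_network_edges(
    path: str | Path, scale: str = "partial_correlation"
) -> WeightedNetwork:
    df = pd.read_csv(path, sep="\t")
    names = sorted(set(df["node_i"]) | set(df["node_j"]))
    idx = {v: i for i, v in enumerate(names)}
    W = np.zeros((len(names), len(names)))
    for _, row in df.iterrows():
        i, j = idx[row["node_i"]], idx[row["node_j"]]
        W[i, j] = W[j, i] = float(row["weight"])
    return WeightedNetwork(W, names, scale=scale)


def model_to_dict(model, failures: list[FailureRecord] | None = None) -> dict:
    """JSON-serializable summary of a fitted mixture."""
    names = model.variable_names_
    return {
        "K": int(model.n_components),
        "variable_names": names,
        "proportions": model.weights_.tolist(),
        "means": model.means_.tolist(),
        "covariances": model.covariances_.tolist(),
        "graphs": [
            [[names[i], names[j]] for i, j in g.edge_list()] for g in model.graphs_
        ],
        "log_likelihood": float(model.log_likelihood_),
        "penalized_log_likelihood": float(model.penalized_log_likelihood_),
        "bic": float(model.bic_),
        "n_parameters": int(model.n_parameters_),
        "n_iterations": int(model.n_iter_),
        "converged": bool(model.converged_),
        "seed": int(model.seed_),
        "failures": [
            {"K": f.K, "reason": f.reason, "detail": f.detail} for f in failures or []
        ],
    }


def write_model_json(model, failures, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model, failures), fh, indent=2, sort_keys=True)
        fh.write("\n")
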