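"""Readers and writers for expression matrices, systems and networks.

Formats are deliberately plain: delimited text (comma or tab, auto-detected)
for expression matrices and adjacency matrices, SIF edge lists for network
topology, JSON for configuration echoes and solution sidecars.  Numbers are
written with 12 significant digits, "." decimal, no thousands separators.
"""

from __future__ import annotations

import csv
import json
import os
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml
from numpy.typing import NDArray

from .kalman import TimeVaryingNetwork
from .linear_sparse import SparseSolution, UnderdeterminedSystem

__all__ = [
    "read_expression",
    "write_expression",
    "read_epochs",
    "read_system",
    "write_network",
    "write_solution",
    "write_run_config",
]

FLOAT_FMT = "%.12g"


def _sniff_sep(path: str | os.PathLike) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(4096)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def read_expression(
    path: str | os.PathLike,
) -> tuple[list[str], NDArray[np.float64], list[str]]:
    """Read a genes x samples expression table.

    First column holds gene identifiers, remaining columns are numeric time
    samples; the delimiter (comma or tab) is auto-detected.  Returns
    ``(gene_names, matrix, sample_labels)``.

    Raises
    ------
    ValueError
        On duplicate gene identifiers (named in the message), non-numeric
        cells, or rows containing NaN (offending genes listed).
    """
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    dupes = df.index[df.index.duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate gene identifiers: {', '.join(map(str, dupes))}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric expression values in {path}: {exc}") from exc
    bad = df.index[np.isnan(values).any(axis=1)].tolist()
    if bad:
        raise ValueError(f"rows with missing values: {', '.join(map(str, bad))}")
    return list(map(str, df.index)), values, list(map(str, df.columns))


def write_expression(
    path: str | os.PathLike,
    gene_names: Sequence[str],
    matrix: NDArray[np.float64],
    sample_labels: Sequence[str] | None = None,
    sep: str = ",",
) -> None:
    """Write a genes x samples expression table (inverse of :func:`read_expression`)."""
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    if sample_labels is None:
        sample_labels = [f"t{j}" for j in range(matrix.shape[1])]
    df = pd.DataFrame(matrix, index=list(gene_names), columns=list(sample_labels))
    df.to_csv(path, sep=sep, float_format=FLOAT_FMT, index_label="gene")


def read_epochs(path: str | os.PathLike) -> list[tuple[int, int]]:
    """Read an epoch partition: a JSON/YAML list of 0-based half-open ranges."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, list):
        raise ValueError("epoch file must contain a list of [start, stop) pairs")
    out = []
    for item in data:
        if not (isinstance(item, (list, tuple)) and len(item) == 2):
            raise ValueError(f"epoch entry {item!r} is not a [start, stop) pair")
        out.append((int(item[0]), int(item[1])))
    return out


def read_system(
    phi_path: str | os.PathLike,
    y_path: str | os.PathLike,
    noise_eps: float = 0.0,
) -> UnderdeterminedSystem:
    """Read an under-determined system from header-free numeric CSV files."""
    phi = np.loadtxt(phi_path, delimiter=_sniff_sep(phi_path), ndmin=2)
    y = np.loadtxt(y_path, delimiter=_sniff_sep(y_path)).ravel()
    return UnderdeterminedSystem(phi, y, noise_eps=noise_eps)


def write_solution(
    sol: SparseSolution,
    out: str | os.PathLike,
) -> tuple[Path, Path]:
    """Write a solution vector as CSV plus a JSON sidecar with its metadata."""
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(out, sol.x[:, None], fmt=FLOAT_FMT, delimiter=",")
    sidecar = out.with_suffix(out.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "residual": sol.residual,
                "zero_set": list(sol.zero_set),
                "num_zeros": sol.num_zeros,
                "converged": sol.converged,
            },
            indent=2,
        )
        + "\n"
    )
    return out, sidecar


def write_network(
    net: TimeVaryingNetwork,
    outdir: str | os.PathLike,
    prefix: str = "epoch",
) -> list[Path]:
    """Write a network sequence as per-epoch adjacency CSVs and SIF edge lists.

    The adjacency CSV carries gene-name headers and signed weights; the SIF
    list holds one ``source <+|-> target`` line per nonzero entry, in
    deterministic row-major gene-name order.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    names = net.gene_names
    for k, A in enumerate(net.A):
        csv_path = outdir / f"{prefix}{k:02d}.csv"
        df = pd.DataFrame(A, index=list(names), columns=list(names))
        df.to_csv(csv_path, float_format=FLOAT_FMT, index_label="gene")
        sif_path = outdir / f"{prefix}{k:02d}.sif"
        with open(sif_path, "w") as fh:
            for i, src in enumerate(names):
                for j, dst in enumerate(names):
                    w = A[i, j]
                    if w != 0.0:
                        sign = "+" if w > 0 else "-"
                        fh.write(f"{src}\t{sign}\t{dst}\n")
        paths += [csv_path, sif_path]
    return paths


def write_run_config(config: dict[str, Any], outdir: str | os.PathLike) -> Path:
    """Echo the effective run configuration as JSON alongside the outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "run_config.json"
    path.write_text(json.dumps(config, indent=2, sort_keys=True, default=str) + "\n")
    return path
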