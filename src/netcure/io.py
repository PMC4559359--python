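"""CSV/TSV matrix readers and writers, edge-list export, report serialization."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import NumericMatrix
from .netinfer import Edge, InferredNetwork
from .outliers import CurationReport

__all__ = [
    "read_matrix",
    "write_matrix",
    "write_edgelist",
    "read_edgelist",
    "report_to_json",
    "MISSING_TOKENS",
]

MISSING_TOKENS = ("", "na", "nan")


def _detect_delimiter(path: str | Path) -> str:
    p = Path(path)
    if p.suffix.lower() in {".tsv", ".tab"}:
        return "\t"
    if p.suffix.lower() == ".csv":
        return ","
    head = p.read_text().splitlines()[0] if p.read_text() else ""
    return "\t" if head.count("\t") >= head.count(",") else ","


def read_matrix(path: str | Path, delimiter: str | None = None) -> NumericMatrix:
    """Read a labelled numeric matrix from CSV/TSV.

    First row holds column ids; a first column of non-numeric content is taken
    as row ids. Empty fields, "NA" and "NaN" (case-insensitive) become the
    missing marker. Ragged rows, non-numeric payload cells and duplicate ids
    are rejected with a diagnostic naming the offender.
    """
    path = Path(path)
    sep = delimiter or _detect_delimiter(path)
    header = path.read_text().splitlines()[0].split(sep)
    dup = sorted({c for c in header if header.count(c) > 1})
    if dup:
        raise ValueError(f"duplicated column name(s): {dup}")
    raw = pd.read_csv(path, sep=sep, header=0, dtype=str, keep_default_na=False,
                      skip_blank_lines=True)

    def parse_cell(text: str):
        t = text.strip()
        if t.lower() in MISSING_TOKENS:
            return np.nan
        try:
            return float(t)
        except ValueError:
            return None

    # row-id autodetection: any unparseable cell in the first column
    first = raw.iloc[:, 0].astype(str)
    has_row_ids = any(parse_cell(t) is None for t in first)
    if has_row_ids:
        row_ids = [t.strip() for t in first]
        if len(set(row_ids)) != len(row_ids):
            raise ValueError("duplicated row ids")
        body = raw.iloc[:, 1:]
    else:
        row_ids = [f"r{i}" for i in range(len(raw))]
        body = raw

    n, p = body.shape
    if p == 0:
        raise ValueError("no data columns found")
    values = np.empty((n, p))
    for j, col in enumerate(body.columns):
        for i, text in enumerate(body[col].astype(str)):
            v = parse_cell(text)
            if v is None:
                raise ValueError(
                    f"non-numeric cell at row {row_ids[i]!r}, column {col!r}: {text!r}"
                )
            values[i, j] = v
    return NumericMatrix(values, row_ids, [str(c) for c in body.columns])


def write_matrix(X: NumericMatrix, path: str | Path, delimiter: str | None = None) -> None:
    """Write a matrix as CSV/TSV at full float precision (round-trip safe)."""
    path = Path(path)
    sep = delimiter or ("\t" if path.suffix.lower() in {".tsv", ".tab"} else ",")
    df = X.to_dataframe()
    df.index.name = "id"
    df.to_csv(path, sep=sep, float_format="%.17g", na_rep="NA")


def write_edgelist(network: InferredNetwork, path: str | Path, fmt: str = "tsv") -> None:
    """Write edges sorted by (source, target); formats: tsv, sif."""
    path = Path(path)
    edges = sorted(network.edges, key=lambda e: (e.source, e.target))
    if fmt == "tsv":
        lines = ["source\ttarget\tstrength\tdirection\tlag"]
        lines += [f"{e.source}\t{e.target}\t{e.strength!r}\t{e.direction}\t{e.lag}"
                  for e in edges]
    elif fmt == "sif":
        lines = [f"{e.source} mi {e.target}" for e in edges]
    else:
        raise ValueError(f"unknown edge-list format {fmt!r}")
    path.write_text("\n".join(lines) + "\n")


def read_edgelist(path: str | Path) -> InferredNetwork:
    """Read a TSV edge list written by :func:`write_edgelist`."""
    df = pd.read_csv(path, sep="\t")
    edges = [Edge(str(r.source), str(r.target), float(r.strength),
                  str(r.direction), int(r.lag)) for r in df.itertuples()]
    variables = sorted({e.source for e in edges} | {e.target for e in edges})
    return InferredNetwork(variables, edges)


def report_to_json(report: CurationReport) -> str:
    """Serialize a curation report (records, limits, rounds) to JSON."""

    def convert(obj):
        if dataclasses.is_dataclass(obj):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        if isinstance(obj, dict):
            return {k: convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        return obj

    payload = convert(report)
    payload.pop("t2", None)
    payload.pop("spe", None)
    for lim in payload.get("limits", []):
        lim.pop("per_subset_limits", None)
    return json.dumps(payload, indent=2)
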