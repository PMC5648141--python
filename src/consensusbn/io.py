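"""Readers and writers for every text format the pipeline touches.

All tabular formats are plain UTF-8 with a mandatory header row.  Writers
prepend ``#``-prefixed metadata comment lines (version, seed, parameters);
readers skip them.  The prior-knowledge matrix CSV mirrors the published
supplementary layout: first column the publication identifier, remaining
columns 0/1 group indicators under group-name headers.  The consensus CSV
is a square labelled integer matrix; the reader accepts either the full
symmetric form or upper-triangle-only storage and canonicalizes to
symmetric.
"""

from __future__ import annotations

import csv
import io as _io
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from consensusbn import __version__ as _version
from consensusbn.consensus import ConsensusNetwork, EdgeClassification
from consensusbn.corpus import AbstractRecord, GeneGroup, PriorKnowledgeMatrix
from consensusbn.k2 import DirectedNetwork
from consensusbn.stability import StabilityReport

__all__ = [
    "read_prior_matrix",
    "write_prior_matrix",
    "read_consensus",
    "write_consensus",
    "read_corpus",
    "write_corpus",
    "read_medline",
    "read_groups",
    "write_groups",
    "write_adjacency",
    "write_edges",
    "read_reference_edges",
    "write_stability_report",
]


def _metadata_lines(meta: Mapping[str, object] | None) -> str:
    lines = [f"# consensusbn {_version}"]
    for k, v in (meta or {}).items():
        lines.append(f"# {k}={v}")
    return "\n".join(lines) + "\n"


def _read_table(path: str | Path, sep: str = ",") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#", dtype=str,
                       keep_default_na=False, skip_blank_lines=True)


# --------------------------------------------------------------------------
# prior-knowledge matrix

def write_prior_matrix(
    matrix: PriorKnowledgeMatrix,
    path: str | Path,
    meta: Mapping[str, object] | None = None,
) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(_metadata_lines(meta))
        writer = csv.writer(fh)
        writer.writerow(["pub_id", *matrix.group_names])
        for pid, row in zip(matrix.row_ids, matrix.values):
            writer.writerow([pid, *row.tolist()])


def read_prior_matrix(path: str | Path) -> PriorKnowledgeMatrix:
    """Parse a prior-knowledge CSV; every indicator cell must be 0 or 1."""
    df = _read_table(path)
    if df.shape[1] < 3:
        raise ValueError("prior matrix needs an id column and >= 2 groups")
    row_ids = df.iloc[:, 0].astype(str).tolist()
    group_names = [str(c) for c in df.columns[1:]]
    raw = np.char.strip(df.iloc[:, 1:].to_numpy(dtype=str))
    bad = ~np.isin(raw, ("0", "1"))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"non-binary cell {raw[r, c]!r} at row {row_ids[r]!r}, "
            f"column {group_names[c]!r}"
        )
    values = (raw == "1").astype(np.int8)
    return PriorKnowledgeMatrix(row_ids=row_ids, group_names=group_names,
                                values=values)


# --------------------------------------------------------------------------
# consensus network

def write_consensus(
    network: ConsensusNetwork,
    path: str | Path,
    meta: Mapping[str, object] | None = None,
) -> None:
    """Write the full symmetric labelled matrix, plus ensemble-size metadata."""
    path = Path(path)
    meta = {"n_networks": network.n_networks, **(meta or {})}
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(_metadata_lines(meta))
        writer = csv.writer(fh)
        writer.writerow(["", *network.group_names])
        for name, row in zip(network.group_names, network.weights):
            writer.writerow([name, *row.tolist()])


def read_consensus(path: str | Path) -> ConsensusNetwork:
    """Parse a consensus CSV, accepting symmetric or upper-triangular storage."""
    path = Path(path)
    n_networks = None
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                if "n_networks=" in line:
                    n_networks = int(line.split("n_networks=")[1].strip())
            else:
                break
    df = _read_table(path)
    group_names = [str(c) for c in df.columns[1:]]
    if len(df) != len(group_names):
        raise ValueError(
            f"consensus matrix is not square: {len(df)} rows, "
            f"{len(group_names)} columns"
        )
    try:
        W = df.iloc[:, 1:].to_numpy(dtype=np.int64)
    except ValueError as exc:
        raise ValueError(f"non-integer entry in consensus matrix: {exc}") from exc
    if (W < 0).any():
        raise ValueError("consensus weights must be non-negative")
    if np.diagonal(W).any():
        raise ValueError("consensus diagonal must be zero")
    lower = np.tril(W, k=-1)
    if not lower.any():
        W = W + W.T  # upper-triangle-only storage
    elif not np.array_equal(W, W.T):
        raise ValueError("matrix is neither symmetric nor upper-triangular")
    return ConsensusNetwork(
        weights=W,
        n_networks=n_networks if n_networks is not None else int(W.max()),
        group_names=group_names,
    )


# --------------------------------------------------------------------------
# corpus and groups

_ESCAPES = {"\\": "\\\\", "\t": "\\t", "\n": "\\n", "\r": "\\r"}


def _escape(text: str) -> str:
    for raw, esc in _ESCAPES.items():
        text = text.replace(raw, esc)
    return text


def _unescape(text: str) -> str:
    out, i = [], 0
    while i < len(text):
        if text[i] == "\\" and i + 1 < len(text):
            nxt = text[i + 1]
            out.append({"\\": "\\", "t": "\t", "n": "\n", "r": "\r"}.get(nxt, nxt))
            i += 2
        else:
            out.append(text[i])
            i += 1
    return "".join(out)


def write_corpus(records: Sequence[AbstractRecord], path: str | Path) -> None:
    """Tab-separated corpus: pub_id, title, abstract (tabs/newlines escaped)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("pub_id\ttitle\tabstract\n")
        for rec in records:
            fh.write(
                f"{rec.pub_id}\t{_escape(rec.title)}\t{_escape(rec.abstract)}\n"
            )


def read_corpus(path: str | Path) -> list[AbstractRecord]:
    records = []
    with Path(path).open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["pub_id", "title", "abstract"]:
            raise ValueError("corpus file must have pub_id/title/abstract header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"line {lineno}: expected 3 tab-separated fields")
            records.append(
                AbstractRecord(parts[0], _unescape(parts[1]), _unescape(parts[2]))
            )
    return records


def read_medline(path: str | Path) -> list[AbstractRecord]:
    """Parse MEDLINE flat-file records using their PMID, TI and AB fields.

    Continuation lines (indented) are folded with single spaces, as in the
    format NCBI serves for text downloads.
    """
    records: list[AbstractRecord] = []
    fields: dict[str, str] = {}
    tag = None

    def flush() -> None:
        if fields.get("PMID"):
            records.append(
                AbstractRecord(
                    pub_id=fields["PMID"],
                    title=fields.get("TI", ""),
                    abstract=fields.get("AB", ""),
                )
            )

    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                if fields:
                    flush()
                    fields, tag = {}, None
                continue
            if line.startswith("      ") and tag:
                fields[tag] += " " + line.strip()
            elif len(line) >= 6 and line[4:6] == "- ":
                tag = line[:4].strip()
                value = line[6:]
                fields[tag] = (fields[tag] + " " + value) if tag in fields else value
    if fields:
        flush()
    return records


def read_groups(path: str | Path, sep: str = "\t") -> list[GeneGroup]:
    """Two-column file (group_name, member_term); order defines node indices."""
    df = _read_table(path, sep=sep)
    if list(df.columns[:2]) != ["group_name", "member_term"]:
        raise ValueError("groups file must have group_name/member_term header")
    members: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        members.setdefault(str(row.iloc[0]), []).append(str(row.iloc[1]))
    return [
        GeneGroup(name=name, members=terms, node_index=i)
        for i, (name, terms) in enumerate(members.items())
    ]


def write_groups(groups: Sequence[GeneGroup], path: str | Path,
                 sep: str = "\t") -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"group_name{sep}member_term\n")
        for g in groups:
            for m in g.members:
                fh.write(f"{g.name}{sep}{m}\n")


# --------------------------------------------------------------------------
# learned structures, edges, reports

def write_adjacency(
    network: DirectedNetwork,
    path: str | Path,
    group_names: Sequence[str] | None = None,
    meta: Mapping[str, object] | None = None,
) -> None:
    """Square 0/1 CSV adjacency with group-name header row and column."""
    n = network.n_nodes
    names = list(group_names) if group_names else [f"G{i}" for i in range(n)]
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        fh.write(_metadata_lines(meta))
        writer = csv.writer(fh)
        writer.writerow(["", *names])
        for name, row in zip(names, network.adjacency):
            writer.writerow([name, *row.tolist()])


def write_edges(
    network: ConsensusNetwork,
    edges: Iterable[tuple[int, int]],
    path: str | Path,
    classifications: Sequence[EdgeClassification] | None = None,
    meta: Mapping[str, object] | None = None,
) -> None:
    """Filtered edge list TSV: node_a, node_b, weight, resolution[, label]."""
    labels = (
        {c.edge: c.label for c in classifications} if classifications else None
    )
    mx = max(network.max_weight, 1)
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(_metadata_lines(meta))
        cols = ["node_a", "node_b", "weight", "resolution"]
        if labels is not None:
            cols.append("classification")
        fh.write("\t".join(cols) + "\n")
        for a, b in sorted(edges):
            w = int(network.weights[a, b])
            row = [
                network.group_names[a],
                network.group_names[b],
                str(w),
                f"{w / mx:.6f}",
            ]
            if labels is not None:
                row.append(labels.get((a, b), ""))
            fh.write("\t".join(row) + "\n")


def read_reference_edges(
    path: str | Path,
    name_to_index: Mapping[str, int],
) -> dict[str, set[tuple[int, int]]]:
    """Reference pathway edges TSV (pathway, node_a, node_b) -> index pairs."""
    df = _read_table(path, sep="\t")
    if list(df.columns[:3]) != ["pathway", "node_a", "node_b"]:
        raise ValueError("reference file must have pathway/node_a/node_b header")
    out: dict[str, set[tuple[int, int]]] = {}
    for _, row in df.iterrows():
        a = name_to_index[str(row.iloc[1])]
        b = name_to_index[str(row.iloc[2])]
        out.setdefault(str(row.iloc[0]), set()).add((min(a, b), max(a, b)))
    return out


def write_stability_report(
    report: StabilityReport,
    path: str | Path,
    meta: Mapping[str, object] | None = None,
) -> None:
    """Kappa grid CSV: test_id, resolution, a, b, c, d, kappa."""
    meta = {"protocol": report.protocol, "seed": report.seed, **(meta or {})}
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        fh.write(_metadata_lines(meta))
        report.to_frame().to_csv(fh, index=False)
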