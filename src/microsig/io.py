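"""Readers and writers for the pipeline's plain-text interchange formats.

Everything is TSV/CSV/GMT/Newick/JSON/YAML: at this study's scale
(thousands of genes, about a dozen populations) plain text is sufficient
and keeps every artefact diffable. Parsers are strict: ragged rows,
non-numeric cells and duplicate gene names are reported with their line
number, and CRLF and LF inputs parse identically.
"""
from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .diffexpr import ExpressionMatrix
from .enrichment import GeneSet
from .signatures import DendrogramSpec, SignatureSet, to_newick

FLOAT_FORMAT = "%.10g"


class ParseError(ValueError):
    """Malformed interchange file; message carries the offending line number."""


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _read_labelled_matrix(path: str | Path) -> pd.DataFrame:
    """Strictly parse a delimited matrix: header row, first column row names."""
    path = Path(path)
    sep = _sep_for(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=sep)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: file is empty") from None
        width = len(header)
        if width < 2:
            raise ParseError(f"{path}: line 1: header must name at least one column")
        columns = header[1:]
        names: list[str] = []
        seen: set[str] = set()
        rows: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and row[0] == ""):
                continue
            if len(row) != width:
                raise ParseError(
                    f"{path}: line {lineno}: expected {width} fields, found {len(row)}"
                )
            name = row[0]
            if name in seen:
                raise ParseError(f"{path}: line {lineno}: duplicate gene {name!r}")
            seen.add(name)
            try:
                values = [float(x) for x in row[1:]]
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-numeric cell ({exc})") from None
            names.append(name)
            rows.append(values)
    if not rows:
        raise ParseError(f"{path}: no data rows")
    return pd.DataFrame(rows, index=names, columns=columns)


def infer_conditions(samples: Sequence[str]) -> dict[str, str]:
    """Condition labels from sample names of the form ``<label>_<index>``."""
    out = {}
    for s in samples:
        if "_" not in s:
            raise ParseError(f"sample {s!r} has no '<condition>_<index>' form")
        out[s] = s.rsplit("_", 1)[0]
    return out


def read_matrix(path: str | Path, kind: str = "expression") -> ExpressionMatrix | SignatureSet:
    """Read a typed matrix; ``kind`` is ``expression`` or ``signature``.

    Both layouts have genes in rows; an expression file's header names
    samples (conditions inferred from the ``<label>_<i>`` sample names), a
    signature file's header names populations (transposed on read so the
    in-memory object is populations x genes).
    """
    frame = _read_labelled_matrix(path)
    if kind == "expression":
        return ExpressionMatrix(values=frame, condition=infer_conditions(frame.columns))
    if kind == "signature":
        return SignatureSet(values=frame.T)
    raise ValueError(f"unknown matrix kind {kind!r}")


def write_matrix(obj: ExpressionMatrix | SignatureSet, path: str | Path) -> None:
    """Write genes-in-rows TSV/CSV (signatures are transposed on write)."""
    path = Path(path)
    frame = obj.values if isinstance(obj, ExpressionMatrix) else obj.values.T
    frame.to_csv(path, sep=_sep_for(path), float_format=FLOAT_FORMAT, index_label="gene")


def read_ct_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    table = pd.read_csv(path, sep=_sep_for(path))
    from .qpcr import validate_ct_table

    return validate_ct_table(table)


def write_ct_table(table: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    table.to_csv(path, sep=_sep_for(path), float_format=FLOAT_FORMAT, index=False)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Standard GMT: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = []
    with open(Path(path), newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {lineno}: GMT rows need name, description, >=1 gene")
            genes = [g for g in fields[2:] if g]
            if len(set(genes)) != len(genes):
                raise ParseError(f"{path}: line {lineno}: duplicate genes in set {fields[0]!r}")
            sets.append(GeneSet(name=fields[0], genes=frozenset(genes)))
    if not sets:
        raise ParseError(f"{path}: no gene sets")
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path, description: str = "synthetic") -> None:
    with open(Path(path), "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, description, *sorted(gs.genes)]) + "\n")


def read_rank(path: str | Path) -> pd.Series:
    """Two-column (gene, score) TSV, assumed already ordered."""
    frame = _read_labelled_matrix(path)
    return pd.Series(frame.iloc[:, 0].to_numpy(dtype=float), index=frame.index, name="score")


def write_rank(scores: pd.Series, path: str | Path) -> None:
    scores.rename("score").to_csv(Path(path), sep="\t", float_format=FLOAT_FORMAT, index_label="gene")


def write_newick(spec: DendrogramSpec, path: str | Path) -> None:
    Path(path).write_text(to_newick(spec) + "\n")


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def sha256_of(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
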