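"""FASTA and table I/O.

FASTA parsing goes through Bio.SeqIO; this layer adds the normalization
and error contracts the rest of the package relies on: ids are the first
whitespace-delimited header token, sequences are uppercased with U -> T,
duplicate ids and empty/malformed files are errors, input order is kept.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO


class FastaError(ValueError):
    """Malformed, empty, or duplicate-id FASTA input."""


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ordered ``(id, sequence)`` pairs."""
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaError(
                        f"{path}: line {lineno}: sequence data before first header"
                    )
                break
        else:
            raise FastaError(f"{path}: empty FASTA file")
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq).upper().replace("U", "T")))
    if not records:
        raise FastaError(f"{path}: no FASTA records found")
    return records


def write_fasta(
    records: Iterable[tuple[str, str]],
    path: str | Path,
    width: int = 70,
    comment: str | None = None,
) -> None:
    """Write ``(id, sequence)`` pairs as wrapped FASTA.

    *comment* (e.g. the simulation seed) is appended to the first header
    after the id, so provenance travels with the file.
    """
    with open(path, "w") as handle:
        for i, (rid, seq) in enumerate(records):
            header = f">{rid}"
            if comment and i == 0:
                header += f" {comment}"
            handle.write(header + "\n")
            for start in range(0, len(seq), width):
                handle.write(seq[start : start + width] + "\n")


def _format_cell(value, precision: int | None) -> str:
    if value is None:
        return "N/A"
    if isinstance(value, float):
        if math.isnan(value):
            return "N/A"
        if precision is not None:
            return f"{value:.{precision}f}"
        return repr(value)
    return str(value)


def render_table(
    table: pd.DataFrame, fmt: str = "tsv", precision: int | None = 3
) -> str:
    """Render a DataFrame as TSV or a markdown pipe table.

    Floats are shown with *precision* decimals (``None`` = full precision);
    NaN/None become ``N/A``.  Output is deterministic for identical input.
    """
    header = list(table.columns)
    body = [
        [_format_cell(v, precision) for v in row]
        for row in table.itertuples(index=False)
    ]
    if fmt == "tsv":
        lines = ["\t".join(header)] + ["\t".join(row) for row in body]
    elif fmt == "markdown":
        widths = [
            max(len(h), *(len(r[i]) for r in body)) if body else len(h)
            for i, h in enumerate(header)
        ]
        def fmt_row(cells):
            return "| " + " | ".join(c.ljust(w) for c, w in zip(cells, widths)) + " |"
        lines = [fmt_row(header), fmt_row(["-" * w for w in widths])]
        lines += [fmt_row(row) for row in body]
    else:
        raise ValueError(f"unknown table format {fmt!r}; expected tsv or markdown")
    return "\n".join(lines) + "\n"


def write_table(
    table: pd.DataFrame,
    path: str | Path,
    fmt: str = "tsv",
    precision: int | None = 3,
) -> None:
    Path(path).write_text(render_table(table, fmt, precision), encoding="utf-8")


def read_pairs_manifest(path: str | Path) -> pd.DataFrame:
    """Read a TSV manifest with columns id_a, id_b (gene-pair matching)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"id_a", "id_b"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    return df


def collect_alignment_paths(path: str | Path) -> list[Path]:
    """A single FASTA path, or every .fa/.fasta/.fna file in a directory."""
    path = Path(path)
    if path.is_dir():
        paths = sorted(
            p for p in path.iterdir() if p.suffix.lower() in (".fa", ".fasta", ".fna")
        )
        if not paths:
            raise FastaError(f"{path}: directory contains no FASTA files")
        return paths
    return [path]
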