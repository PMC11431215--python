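"""Reading and writing coding sets (plain text and FASTA) and reports."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .constraints import CodewordError, ValidationReport, canonical_codeword

FASTA_LINE_WIDTH = 70


def read_code_set(path, fmt: Optional[str] = None) -> list[str]:
    """Read codewords from a file.

    ``fmt`` is ``"fasta"`` or ``"txt"``; when omitted it is sniffed from the
    suffix (``.fa``/``.fasta``) and then from a leading ``>``.  Plain text is
    one codeword per line with ``#``-prefixed comment lines ignored.
    Malformed codewords raise :class:`CodewordError` naming the line.
    """
    path = Path(path)
    if fmt is None:
        if path.suffix.lower() in (".fa", ".fasta", ".fna"):
            fmt = "fasta"
        else:
            with open(path) as fh:
                first = fh.readline()
            fmt = "fasta" if first.startswith(">") else "txt"

    words: list[str] = []
    if fmt == "fasta":
        for record in SeqIO.parse(str(path), "fasta"):
            try:
                words.append(canonical_codeword(str(record.seq)))
            except CodewordError as exc:
                raise CodewordError(f"{path}, record {record.id!r}: {exc}") from exc
    elif fmt == "txt":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                stripped = line.strip()
                if not stripped or stripped.startswith("#"):
                    continue
                try:
                    words.append(canonical_codeword(stripped))
                except CodewordError as exc:
                    raise CodewordError(f"{path}, line {lineno}: {exc}") from exc
    else:
        raise ValueError(f"unknown format {fmt!r} (expected 'fasta' or 'txt')")
    return words


def write_code_set(
    words: Sequence[str],
    path,
    fmt: str = "txt",
    n: Optional[int] = None,
    d: Optional[int] = None,
) -> None:
    """Write codewords as plain text or FASTA.

    FASTA headers follow ``>cw_<index> n=<n> d=<d>``; sequence lines wrap at
    70 columns (a common dialect default, moot for short codewords).
    """
    path = Path(path)
    if fmt == "txt":
        with open(path, "w") as fh:
            fh.write(f"# coding set, {len(words)} codewords\n")
            for w in words:
                fh.write(w + "\n")
    elif fmt == "fasta":
        records = []
        for i, w in enumerate(words):
            desc = ""
            if n is not None:
                desc += f"n={n}"
            if d is not None:
                desc += f" d={d}" if desc else f"d={d}"
            records.append(SeqRecord(Seq(w), id=f"cw_{i}", description=desc))
        with open(path, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=FASTA_LINE_WIDTH)
            writer.write_file(records)
    else:
        raise ValueError(f"unknown format {fmt!r} (expected 'fasta' or 'txt')")


def write_validation_report(report: ValidationReport, path) -> None:
    """Write a validation report as machine-readable JSON."""
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=1)
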