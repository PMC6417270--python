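"""Sequence records, FASTA I/O and the tool's tabular report format.

Proteomes are consumed as translated peptide FASTA.  On input every
sequence is normalized to a 21-letter alphabet (the 20 canonical amino
acids plus ``X`` for anything ambiguous or unknown); a trailing stop
(``*``) is stripped.  All coordinates reported anywhere in the package
are 1-based inclusive, matching the residue numbering conventions of
the structural literature (e.g. Cys36, Arg189, Glu196 in AaeUPO).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 canonical one-letter amino-acid codes.
CANONICAL = "ACDEFGHIKLMNPQRSTVWY"

#: Alphabet after normalization.
ALPHABET = CANONICAL + "X"

_ALPHABET_SET = frozenset(ALPHABET)


class FastaParseError(ValueError):
    """Raised when a file is not parseable as FASTA."""


class DuplicateIdError(ValueError):
    """Raised when two records in one collection share an id."""


def normalize_residues(raw: str) -> str:
    """Map a raw peptide string onto the 21-letter alphabet.

    Uppercases, strips a single terminal stop codon (``*``), and maps
    every character outside the canonical 20 (ambiguity codes B/Z/J,
    the rare U/O, internal stops, gap characters, digits...) to ``X``.
    Idempotent: normalizing twice equals normalizing once.
    """
    s = raw.upper()
    if s.endswith("*"):
        s = s[:-1]
    return "".join(c if c in _ALPHABET_SET else "X" for c in s)


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence with provenance.

    Parameters
    ----------
    id : str
        Unique token within a collection.
    residues : str
        Uppercase one-letter residues over the 21-letter alphabet.
    description : str
        Free text carried from the FASTA header.
    source : str
        Originating file path, or ``"synthetic"``.
    """

    id: str
    residues: str
    description: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.residues) - _ALPHABET_SET
        if bad:
            raise ValueError(
                f"record {self.id!r}: residues outside alphabet: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AnnotationRow:
    """One key/value annotation attached to a record at a pipeline stage."""

    record_id: str
    stage: str  # homology | cluster | grammar | classify
    key: str
    value: str | int | float


def _check_unique_ids(records: Sequence[ProteinRecord]) -> None:
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise DuplicateIdError(f"duplicate record id: {r.id!r}")
        seen.add(r.id)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a peptide FASTA file into normalized :class:`ProteinRecord` s.

    File order is preserved.  An empty file yields an empty list with a
    logged warning; duplicate ids raise :class:`DuplicateIdError`; text
    before the first header raises :class:`FastaParseError` with the
    offending line number.
    """
    path = Path(path)
    # SeqIO silently skips junk before the first '>'; detect it here so the
    # error can name a line number.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: expected FASTA header, got {line.strip()[:40]!r}"
                )
            break

    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = normalize_residues(str(rec.seq))
        if not residues:
            raise FastaParseError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(
            ProteinRecord(
                id=rec.id,
                residues=residues,
                description=rec.description[len(rec.id):].strip(),
                source=str(path),
            )
        )
    if not records:
        logger.warning("no sequences found in %s", path)
    _check_unique_ids(records)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as 60-column-wrapped FASTA (round-trips with read_fasta)."""
    path = Path(path)
    with open(path, "w") as fh:
        for r in records:
            header = f">{r.id}"
            if r.description:
                header += f" {r.description}"
            fh.write(header + "\n")
            for i in range(0, len(r.residues), 60):
                fh.write(r.residues[i : i + 60] + "\n")


_REPORT_HEADER = ("record_id", "stage", "key", "value")


def write_report(
    rows: Iterable[AnnotationRow], path: str | Path, fmt: str = "tsv"
) -> None:
    """Write annotation rows as a deterministic TSV (or JSON) report.

    Rows are sorted by (record id, stage, key, value) so that logically
    identical runs produce byte-identical files regardless of the order
    annotations were collected in.
    """
    ordered = sorted(rows, key=lambda r: (r.record_id, r.stage, r.key, str(r.value)))
    path = Path(path)
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(_REPORT_HEADER) + "\n")
            for r in ordered:
                fh.write(f"{r.record_id}\t{r.stage}\t{r.key}\t{r.value}\n")
    elif fmt == "json":
        payload = [
            {"record_id": r.record_id, "stage": r.stage, "key": r.key, "value": r.value}
            for r in ordered
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")
    else:
        raise ValueError(f"unknown report format: {fmt!r}")


def read_report(path: str | Path) -> list[AnnotationRow]:
    """Read a TSV report written by :func:`write_report`."""
    rows: list[AnnotationRow] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _REPORT_HEADER:
            raise ValueError(f"{path}: unexpected report header {header}")
        for line in fh:
            rid, stage, key, value = line.rstrip("\n").split("\t", 3)
            rows.append(AnnotationRow(rid, stage, key, value))
    return rows
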