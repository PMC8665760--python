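"""FASTA and TSV input/output.

FASTA writing preserves the labeled-header dialect of the synthetic
generator verbatim, so simulate -> write -> read round-trips exactly.
"""

from __future__ import annotations

from pathlib import Path

from .records import SequenceRecord


class FastaError(ValueError):
    pass


def read_fasta(path) -> list[SequenceRecord]:
    """Read FASTA; tolerates CRLF; errors name duplicate ids and bad content."""
    text = Path(path).read_text()
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: str | None = None
    chunks: list[str] = []

    def flush():
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FastaError(f"record {header.split()[0]!r}: empty sequence")
        rec = SequenceRecord.from_header(header, seq)
        if rec.id in seen:
            raise FastaError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(rec)

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            header = line[1:].strip()
            if not header:
                raise FastaError(f"line {lineno}: empty FASTA header")
            chunks = []
        else:
            if header is None:
                raise FastaError(f"line {lineno}: sequence data before any header")
            chunks.append(line)
    flush()
    if not records:
        raise FastaError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: list[SequenceRecord], path, width: int = 60) -> None:
    if not records:
        raise FastaError("refusing to write an empty record set")
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.header()}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def write_truth_table(truth: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for rec_id in truth:
            fh.write(f"{rec_id}\t{truth[rec_id]}\n")


def read_truth_table(path) -> dict[str, str]:
    truth: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'id<TAB>family'")
        truth[parts[0]] = parts[1]
    return truth
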