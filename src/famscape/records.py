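"""Sequence records and the labeled-FASTA header dialect.

Synthetic records carry their ground truth in the FASTA header:

    >id family=<label> motif=<p1,p2,...>

with 0-based motif positions. Both annotations are optional; plain headers
parse to records with no truth labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class SequenceRecord:
    id: str
    seq: str
    family: str | None = None
    motif_positions: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid record id {self.id!r}")
        if not self.seq:
            raise ValueError(f"record {self.id}: empty sequence")
        for p in self.motif_positions:
            if not 0 <= p < len(self.seq):
                raise ValueError(f"record {self.id}: motif position {p} out of range")

    def __len__(self) -> int:
        return len(self.seq)

    def header(self) -> str:
        parts = [self.id]
        if self.family is not None:
            parts.append(f"family={self.family}")
        if self.motif_positions:
            parts.append("motif=" + ",".join(str(p) for p in self.motif_positions))
        return " ".join(parts)

    @classmethod
    def from_header(cls, header: str, seq: str) -> "SequenceRecord":
        fields = header.split()
        rec_id = fields[0]
        family = None
        motif: tuple[int, ...] = ()
        for f in fields[1:]:
            if f.startswith("family="):
                family = f[len("family="):]
            elif f.startswith("motif="):
                body = f[len("motif="):]
                if body:
                    motif = tuple(int(x) for x in body.split(","))
        return cls(id=rec_id, seq=seq, family=family, motif_positions=motif)
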