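"""Core sequence and interval types shared by every pipeline stage.

All internal coordinates are 0-based half-open on the forward strand of the
named sequence. Conversions to 1-based inclusive (GFF3) happen only in the
:mod:`ltrscout.io` writers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Iterator, Optional, Tuple

NUCLEOTIDES = "ACGTN"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval ``[start, end)`` on a named sequence.

    ``strand`` is ``+``, ``-`` or ``.`` (unknown / not applicable).
    """

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.seq_id:
            raise ValueError("seq_id must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id}"
            )
        if self.strand not in "+-.":
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )

    def shift(self, offset: int) -> "GenomicInterval":
        return replace(self, start=self.start + offset, end=self.end + offset)

    def flipped(self, seq_len: int) -> "GenomicInterval":
        """Map onto the reverse complement of a sequence of length ``seq_len``."""
        strand = {"+": "-", "-": "+", ".": "."}[self.strand]
        return GenomicInterval(self.seq_id, seq_len - self.end, seq_len - self.start, strand)


class GenomeSequence:
    """Ordered collection of named nucleotide sequences (A/C/G/T/N, uppercase).

    Used both for genomes and for small auxiliary sequence sets such as the
    tRNAs screened for primer-binding sites.
    """

    def __init__(self, records: Dict[str, str]):
        seen = {}
        for name, seq in records.items():
            if not name:
                raise ValueError("empty sequence id")
            if name in seen:
                raise ValueError(f"duplicate id {name}")
            if not seq:
                raise ValueError(f"empty sequence for id {name}")
            bad = set(seq) - set(NUCLEOTIDES)
            if bad:
                raise ValueError(
                    f"sequence {name} contains characters outside "
                    f"{NUCLEOTIDES}: {sorted(bad)}"
                )
            seen[name] = seq
        self._records: Dict[str, str] = seen

    @property
    def records(self) -> Dict[str, str]:
        return dict(self._records)

    def ids(self) -> Tuple[str, ...]:
        return tuple(self._records)

    def lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self._records.items()}

    def __getitem__(self, name: str) -> str:
        return self._records[name]

    def __contains__(self, name: str) -> bool:
        return name in self._records

    def __len__(self) -> int:
        return len(self._records)

    def items(self) -> Iterator[Tuple[str, str]]:
        return iter(self._records.items())

    def fetch(self, interval: GenomicInterval) -> str:
        """Sequence under an interval, on the forward strand; reverse
        complemented when the interval's strand is ``-``."""
        seq = self._records[interval.seq_id]
        if interval.end > len(seq):
            raise ValueError(
                f"interval {interval} beyond end of {interval.seq_id} "
                f"({len(seq)} bp)"
            )
        sub = seq[interval.start : interval.end]
        return reverse_complement(sub) if interval.strand == "-" else sub


@dataclass(frozen=True)
class ReadAlignment:
    """A single mapped read; mates of a pair share ``read_id``."""

    read_id: str
    interval: GenomicInterval
    mate_interval: Optional[GenomicInterval] = None
    is_unique: bool = True


@dataclass(frozen=True)
class Fragment:
    """A sequenced template: the union span of a read pair (or a single read)."""

    frag_id: str
    interval: GenomicInterval
    is_unique: bool = True
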