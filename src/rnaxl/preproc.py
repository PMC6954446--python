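"""Read-level preprocessing: adapter trimming, fixed prefix removal, quality filter.

Operates on single-end reads. The canonical chain is
``trim_adapter -> trim_fixed_prefix -> filter_by_quality``; reads failing any
stage are dropped (functions return ``None``).
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Iterator, Optional, Sequence, TextIO, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

READ_ALPHABET = frozenset("ACGTN")

DEFAULT_ADAPTER = "AGATCGGAAGAGC"
DEFAULT_MIN_LEN = 40
DEFAULT_PREFIX_TRIM = 6
DEFAULT_MIN_PHRED = 20
DEFAULT_MAX_LOW_FRAC = 0.04

#: minimum terminal partial-adapter match considered evidence of read-through
MIN_PARTIAL_ADAPTER = 3


@dataclasses.dataclass(frozen=True)
class Read:
    """A single sequencing read: identifier, bases over {A,C,G,T,N}, Phred scores."""

    id: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.id}: {len(self.bases)} bases but {len(self.quals)} quals"
            )
        if not set(self.bases) <= READ_ALPHABET:
            bad = set(self.bases) - READ_ALPHABET
            raise ValueError(f"read {self.id}: illegal characters {sorted(bad)}")
        if any(q < 0 for q in self.quals):
            raise ValueError(f"read {self.id}: negative Phred score")
        object.__setattr__(self, "quals", tuple(self.quals))

    def __len__(self) -> int:
        return len(self.bases)

    def truncated(self, start: int = 0, end: Optional[int] = None) -> "Read":
        return Read(self.id, self.bases[start:end], self.quals[start:end])


def _terminal_partial_match(bases: str, adapter: str) -> Optional[int]:
    """Start index of the longest adapter prefix (>= MIN_PARTIAL_ADAPTER bases)
    that coincides with the end of the read, or None."""
    max_k = min(len(adapter) - 1, len(bases))
    for k in range(max_k, MIN_PARTIAL_ADAPTER - 1, -1):
        if bases.endswith(adapter[:k]):
            return len(bases) - k
    return None


def trim_adapter(
    read: Read, adapter: str = DEFAULT_ADAPTER, min_len: int = DEFAULT_MIN_LEN
) -> Optional[Read]:
    """Remove the suffix starting at the first adapter occurrence.

    A full occurrence anywhere in the read takes priority; otherwise a
    terminal partial match of at least 3 adapter bases at the read end is
    trimmed. Reads shorter than ``min_len`` after trimming are discarded
    (returns ``None``).
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    cut = read.bases.find(adapter)
    if cut < 0:
        partial = _terminal_partial_match(read.bases, adapter)
        cut = partial if partial is not None else len(read)
    if cut < min_len:
        return None
    return read.truncated(0, cut)


def trim_fixed_prefix(read: Read, n: int = DEFAULT_PREFIX_TRIM) -> Optional[Read]:
    """Drop the first ``n`` bases (random-primer / junction bases).

    Returns ``None`` (discard) when the read is shorter than ``n``.
    """
    if n < 0:
        raise ValueError("prefix length must be >= 0")
    if len(read) < n:
        return None
    return read.truncated(n)


def filter_by_quality(
    read: Read,
    min_phred: int = DEFAULT_MIN_PHRED,
    max_low_frac: float = DEFAULT_MAX_LOW_FRAC,
) -> bool:
    """True (keep) unless more than ``max_low_frac`` of bases are below ``min_phred``.

    Zero-length reads are discarded.
    """
    if len(read) == 0:
        return False
    n_low = sum(1 for q in read.quals if q < min_phred)
    return n_low / len(read) <= max_low_frac


def process_read(
    read: Read,
    adapter: str = DEFAULT_ADAPTER,
    min_len: int = DEFAULT_MIN_LEN,
    prefix: int = DEFAULT_PREFIX_TRIM,
    min_phred: int = DEFAULT_MIN_PHRED,
    max_low_frac: float = DEFAULT_MAX_LOW_FRAC,
) -> Optional[Read]:
    """Full preprocessing chain; returns the surviving read or ``None``."""
    trimmed = trim_adapter(read, adapter, min_len)
    if trimmed is None:
        return None
    trimmed = trim_fixed_prefix(trimmed, prefix)
    if trimmed is None:
        return None
    if not filter_by_quality(trimmed, min_phred, max_low_frac):
        return None
    return trimmed


def process_reads(reads: Iterable[Read], **kwargs) -> Iterator[Read]:
    for read in reads:
        out = process_read(read, **kwargs)
        if out is not None:
            yield out


# ---------------------------------------------------------------------------
# FASTQ I/O (Phred+33)

def read_fastq(handle: Union[str, TextIO]) -> Iterator[Read]:
    for rec in SeqIO.parse(handle, "fastq"):
        yield Read(rec.id, str(rec.seq).upper(), tuple(rec.letter_annotations["phred_quality"]))


def write_fastq(reads: Iterable[Read], handle: Union[str, TextIO]) -> int:
    def _records():
        for r in reads:
            rec = SeqRecord(Seq(r.bases), id=r.id, description="")
            rec.letter_annotations["phred_quality"] = list(r.quals)
            yield rec

    return SeqIO.write(_records(), handle, "fastq")
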