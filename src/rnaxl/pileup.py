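"""Alignment pileup: per-position base counts and substitution-rate profiles.

Coordinates are 1-based, fully closed and reference-oriented throughout the
public API (SAM convention); internal numpy arrays are 0-indexed with array
index ``i`` holding position ``i + 1``.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

logger = logging.getLogger(__name__)

BASES = "ACGTN"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# byte value -> base code lookup (unknown bytes count as N)
_CODE_OF_BYTE = np.full(256, BASE_INDEX["N"], dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _CODE_OF_BYTE[ord(_b)] = _i
    _CODE_OF_BYTE[ord(_b.lower())] = _i
_CODE_OF_BYTE[ord("U")] = BASE_INDEX["T"]
_CODE_OF_BYTE[ord("u")] = BASE_INDEX["T"]


def encode_bases(seq: str) -> np.ndarray:
    """Sequence string -> int8 codes (A=0, C=1, G=2, T=3, N=4); U maps to T."""
    return _CODE_OF_BYTE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_bases(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


@dataclasses.dataclass(frozen=True)
class Genome:
    """Reference sequence; held in DNA alphabet, U positions == T positions."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        seq = self.seq.upper().replace("U", "T")
        if not set(seq) <= set(BASES):
            raise ValueError(f"genome {self.id}: non-ACGTN characters")
        object.__setattr__(self, "seq", seq)

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def codes(self) -> np.ndarray:
        return encode_bases(self.seq)

    def base_positions(self, bases: Union[str, Sequence[str]]) -> np.ndarray:
        """1-based positions whose reference base is in ``bases``."""
        want = set(bases)
        codes = self.codes
        mask = np.zeros(len(self), dtype=bool)
        for b in want:
            mask |= codes == BASE_INDEX[b]
        return np.flatnonzero(mask) + 1

    @property
    def u_positions(self) -> np.ndarray:
        """1-based uridine positions (reference T)."""
        return self.base_positions("T")

    @classmethod
    def from_fasta(cls, path: Union[str, Path], record_id: Optional[str] = None) -> "Genome":
        for rec in SeqIO.parse(str(path), "fasta"):
            if record_id is None or rec.id == record_id:
                return cls(rec.id, str(rec.seq))
        raise ValueError(f"record {record_id!r} not found in {path}")

    def to_fasta(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.id}\n")
            for i in range(0, len(self.seq), 70):
                fh.write(self.seq[i : i + 70] + "\n")


@dataclasses.dataclass
class BaseCountTable:
    """Per-position counts of observed A/C/G/T/N. Coverage excludes N."""

    genome_id: str
    counts: np.ndarray  # (L, 5) int64

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 5:
            raise ValueError("counts must be (L, 5)")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    def __len__(self) -> int:
        return self.counts.shape[0]

    @property
    def coverage(self) -> np.ndarray:
        return self.counts[:, :4].sum(axis=1)

    def base_count(self, base: str) -> np.ndarray:
        return self.counts[:, BASE_INDEX[base]]

    def to_frame(self, genome: Genome) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": np.arange(1, len(self) + 1),
                "ref": list(genome.seq),
                **{b: self.counts[:, i] for i, b in enumerate(BASES)},
                "coverage": self.coverage,
            }
        )

    def to_tsv(self, path: Union[str, Path], genome: Genome) -> None:
        self.to_frame(genome).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: Union[str, Path], genome_id: str) -> "BaseCountTable":
        df = pd.read_csv(path, sep="\t")
        return cls(genome_id, df[list(BASES)].to_numpy())

    def merged(self, other: "BaseCountTable") -> "BaseCountTable":
        if other.genome_id != self.genome_id or len(other) != len(self):
            raise ValueError("cannot merge count tables of different genomes")
        return BaseCountTable(self.genome_id, self.counts + other.counts)


@dataclasses.dataclass
class RateProfile:
    """Per-position substitution rate for one event class.

    ``rate`` is NaN (ABSENT) at ineligible positions, at zero coverage, and
    wherever ``coverage_ok`` is False. ``coverage`` is retained for the
    fold-change floor rule.
    """

    genome_id: str
    event: str  # e.g. "T>C" or "mismatch:AC"
    rate: np.ndarray  # (L,) float64, NaN = ABSENT
    coverage: np.ndarray  # (L,) int64
    coverage_ok: np.ndarray  # (L,) bool

    def __post_init__(self) -> None:
        self.rate = np.asarray(self.rate, dtype=np.float64)
        self.coverage = np.asarray(self.coverage, dtype=np.int64)
        self.coverage_ok = np.asarray(self.coverage_ok, dtype=bool)
        if not (len(self.rate) == len(self.coverage) == len(self.coverage_ok)):
            raise ValueError("array length mismatch")

    def __len__(self) -> int:
        return len(self.rate)

    @property
    def present(self) -> np.ndarray:
        return ~np.isnan(self.rate)

    def present_values(self) -> np.ndarray:
        return self.rate[self.present]


def _require_primary(rec: pysam.AlignedSegment) -> bool:
    return not (rec.is_unmapped or rec.is_secondary or rec.is_supplementary)


def _cigar_is_single_match(rec: pysam.AlignedSegment) -> bool:
    ct = rec.cigartuples
    return ct is not None and len(ct) == 1 and ct[0][0] in (0, 7, 8)  # M, =, X


def build_base_counts(
    alignments: Union[str, Path, Iterable[pysam.AlignedSegment]],
    genome: Genome,
) -> BaseCountTable:
    """Pile up primary alignments into a BaseCountTable.

    Only CIGAR match/mismatch columns contribute; insertions, deletions and
    clipped bases are ignored. Records whose CIGAR is inconsistent with the
    read length are skipped with a warning. A reference-id mismatch is an
    error.
    """
    L = len(genome)
    flat = np.zeros(L * 5, dtype=np.int64)

    if isinstance(alignments, (str, Path)):
        af = pysam.AlignmentFile(str(alignments), check_sq=False)
        records: Iterable[pysam.AlignedSegment] = af
    else:
        records = alignments

    # fast path: batch simple single-M records and bincount them together
    batch_starts: list[int] = []
    batch_seqs: list[str] = []
    batch_len: Optional[int] = None

    def _flush() -> None:
        nonlocal batch_starts, batch_seqs, batch_len
        if not batch_starts:
            return
        starts = np.asarray(batch_starts, dtype=np.int64)
        codes = encode_bases("".join(batch_seqs)).reshape(len(batch_starts), batch_len)
        pos = starts[:, None] + np.arange(batch_len, dtype=np.int64)[None, :]
        flat_idx = pos.ravel() * 5 + codes.ravel()
        flat[:] += np.bincount(flat_idx, minlength=L * 5)
        batch_starts, batch_seqs, batch_len = [], [], None

    n_skipped = 0
    for rec in records:
        if not _require_primary(rec):
            continue
        if rec.reference_name != genome.id:
            raise ValueError(
                f"alignment reference {rec.reference_name!r} does not match genome {genome.id!r}"
            )
        seq = rec.query_sequence
        if seq is None:
            n_skipped += 1
            continue
        if rec.infer_query_length() not in (None, len(seq)):
            logger.warning("record %s: CIGAR inconsistent with read length; skipped", rec.query_name)
            n_skipped += 1
            continue
        if _cigar_is_single_match(rec) and rec.reference_start + len(seq) <= L:
            if batch_len is not None and batch_len != len(seq) or len(batch_starts) >= 100_000:
                _flush()
            batch_len = len(seq)
            batch_starts.append(rec.reference_start)
            batch_seqs.append(seq)
            continue
        # general path: aligned pairs restricted to match columns
        for qpos, rpos in rec.get_aligned_pairs(matches_only=True):
            if rpos is None or qpos is None or rpos >= L:
                continue
            flat[rpos * 5 + BASE_INDEX.get(seq[qpos], 4)] += 1
    _flush()

    if n_skipped:
        logger.warning("skipped %d malformed records", n_skipped)
    return BaseCountTable(genome.id, flat.reshape(L, 5))


def transition_profile(
    counts: BaseCountTable, genome: Genome, ref_base: str, alt_base: str
) -> RateProfile:
    """Rate of observing ``alt_base`` at reference ``ref_base`` positions.

    E.g. ``ref_base='T', alt_base='C'`` gives the per-U-position U->C
    transition rate.
    """
    if ref_base == alt_base:
        raise ValueError("ref_base and alt_base must differ")
    codes = genome.codes
    eligible = codes == BASE_INDEX[ref_base]
    cov = counts.coverage
    rate = np.full(len(genome), np.nan)
    ok = eligible & (cov > 0)
    rate[ok] = counts.base_count(alt_base)[ok] / cov[ok]
    return RateProfile(
        genome_id=genome.id,
        event=f"{ref_base}>{alt_base}",
        rate=rate,
        coverage=cov,
        coverage_ok=cov > 0,
    )


def mismatch_profile(
    counts: BaseCountTable, genome: Genome, ref_bases: Union[str, Sequence[str]]
) -> RateProfile:
    """Any-mismatch rate at positions whose reference base is in ``ref_bases``.

    E.g. ``ref_bases='AC'`` gives the per-position A/C mutation rate used for
    single-strandedness probing.
    """
    ref_set = sorted(set(ref_bases))
    if not set(ref_set) <= set("ACGT"):
        raise ValueError("ref_bases must be a subset of ACGT")
    codes = genome.codes
    cov = counts.coverage
    rate = np.full(len(genome), np.nan)
    for b in ref_set:
        sel = (codes == BASE_INDEX[b]) & (cov > 0)
        rate[sel] = (cov[sel] - counts.base_count(b)[sel]) / cov[sel]
    return RateProfile(
        genome_id=genome.id,
        event=f"mismatch:{''.join(ref_set)}",
        rate=rate,
        coverage=cov,
        coverage_ok=cov > 0,
    )
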