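"""Synthetic genomes and read sets with recorded ground truth.

Models the experimental designs the pipeline consumes: paired
crosslinked/control samples differing only in elevated U->C rates at
designated sites, paired DMS+/DMS- samples differing in A/C mismatch rates at
unpaired positions, uniform per-base sequencing error, and fixed minority
variants present in both members of a pair.

Reads are drawn with uniform start positions and emitted either as FASTQ
(constant Q37) or as already-aligned SAM with perfect full-length match
CIGARs, so the pileup stage can be exercised without an external aligner.
All randomness flows through one seeded generator per call; fixed seeds give
byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

import numpy as np
import pandas as pd

from rnaxl.pileup import BASE_INDEX, BASES, Genome, encode_bases
from rnaxl.structure import StructureModel

DEFAULT_READ_LEN = 150
_FASTQ_QUAL_CHAR = chr(37 + 33)  # constant Q37
_CHUNK_READS = 50_000


@dataclasses.dataclass
class TruthTable:
    """Ground truth for one paired simulation.

    crosslink_sites: U position -> extra U->C rate, applied in the test arm only.
    variant_sites:   position -> (alt base, rate), applied in BOTH arms.
    dms_unpaired:    A/C position -> elevated mismatch rate (test arm only).
    base_error:      uniform per-base error rate, all arms.
    """

    crosslink_sites: Dict[int, float] = dataclasses.field(default_factory=dict)
    variant_sites: Dict[int, Tuple[str, float]] = dataclasses.field(default_factory=dict)
    dms_unpaired: Dict[int, float] = dataclasses.field(default_factory=dict)
    base_error: float = 0.0

    def __post_init__(self) -> None:
        rates = list(self.crosslink_sites.values()) + [
            r for _, r in self.variant_sites.values()
        ] + list(self.dms_unpaired.values()) + [self.base_error]
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("all rates must lie in [0, 1]")

    def validate_against(self, genome: Genome) -> None:
        for p in self.crosslink_sites:
            if genome.seq[p - 1] != "T":
                raise ValueError(f"crosslink site {p} is not a U position")
        for p in self.dms_unpaired:
            if genome.seq[p - 1] not in "AC":
                raise ValueError(f"DMS site {p} is not an A/C position")
        for p, (alt, _) in self.variant_sites.items():
            if alt == genome.seq[p - 1]:
                raise ValueError(f"variant at {p} equals the reference base")

    def to_tsv(self, path: Union[str, Path]) -> None:
        rows = [("crosslink", p, r, "C") for p, r in sorted(self.crosslink_sites.items())]
        rows += [("variant", p, r, alt) for p, (alt, r) in sorted(self.variant_sites.items())]
        rows += [("dms_unpaired", p, r, "*") for p, r in sorted(self.dms_unpaired.items())]
        rows += [("base_error", 0, self.base_error, "*")]
        pd.DataFrame(rows, columns=["kind", "position", "rate", "alt"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "TruthTable":
        df = pd.read_csv(path, sep="\t")
        tt = cls()
        for _, row in df.iterrows():
            if row["kind"] == "crosslink":
                tt.crosslink_sites[int(row["position"])] = float(row["rate"])
            elif row["kind"] == "variant":
                tt.variant_sites[int(row["position"])] = (str(row["alt"]), float(row["rate"]))
            elif row["kind"] == "dms_unpaired":
                tt.dms_unpaired[int(row["position"])] = float(row["rate"])
            elif row["kind"] == "base_error":
                tt.base_error = float(row["rate"])
        return tt


@dataclasses.dataclass
class ReadSet:
    """Simulated reads plus everything needed to emit FASTQ/SAM deterministically."""

    genome_id: str
    genome_len: int
    read_len: int
    starts: np.ndarray  # (n,) 0-based reference starts
    seqs: list[str]
    reverse: np.ndarray  # (n,) bool -> SAM flag 16 (SEQ stays reference-oriented)
    params: dict

    def __len__(self) -> int:
        return len(self.seqs)

    def write_sam(self, path: Union[str, Path]) -> None:
        qual = _FASTQ_QUAL_CHAR * self.read_len
        cigar = f"{self.read_len}M"
        with open(path, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:unknown\n")
            fh.write(f"@SQ\tSN:{self.genome_id}\tLN:{self.genome_len}\n")
            for i, (st, seq, rev) in enumerate(zip(self.starts, self.seqs, self.reverse)):
                flag = 16 if rev else 0
                fh.write(
                    f"r{i:07d}\t{flag}\t{self.genome_id}\t{st + 1}\t60\t{cigar}"
                    f"\t*\t0\t0\t{seq}\t{qual}\n"
                )

    def write_fastq(self, path: Union[str, Path]) -> None:
        qual = _FASTQ_QUAL_CHAR * self.read_len
        with open(path, "w") as fh:
            for i, seq in enumerate(self.seqs):
                fh.write(f"@r{i:07d}\n{seq}\n+\n{qual}\n")

    def write_sidecar(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            json.dump(self.params, fh, indent=2, sort_keys=True)
            fh.write("\n")


def make_genome(
    length: int,
    base_composition: Tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
    seed: Optional[int] = None,
    genome_id: str = "synthetic",
) -> Genome:
    """Seeded random genome with the given A/C/G/T composition."""
    comp = np.asarray(base_composition, dtype=float)
    if comp.shape != (4,) or not np.isclose(comp.sum(), 1.0):
        raise ValueError("base_composition must be a 4-vector summing to 1")
    rng = np.random.default_rng(seed)
    codes = rng.choice(4, size=length, p=comp)
    seq = "".join(BASES[c] for c in codes)
    return Genome(genome_id, seq)


def _draw_reads(
    genome: Genome,
    site_rate: np.ndarray,
    site_alt: np.ndarray,
    base_error: float,
    depth: float,
    read_len: int,
    seed: Optional[int],
    reverse_frac: float,
    params: dict,
) -> ReadSet:
    """Vectorized read sampler.

    ``site_rate[i]`` is the per-base probability of the site event at position
    i+1; ``site_alt[i]`` the substituted base code, or -1 for a uniformly
    chosen non-reference base. Conditional on no site event, a uniform error
    at ``base_error`` substitutes a uniformly chosen non-reference base.
    """
    L = len(genome)
    if read_len > L:
        raise ValueError("read_len exceeds genome length")
    gcodes = genome.codes
    if (gcodes > 3).any():
        raise ValueError("simulator requires an N-free genome")
    rng = np.random.default_rng(seed)
    n_reads = int(round(depth * L / read_len))
    starts = rng.integers(0, L - read_len + 1, size=n_reads)
    reverse = (
        rng.random(n_reads) < reverse_frac
        if reverse_frac > 0
        else np.zeros(n_reads, dtype=bool)
    )
    offs = np.arange(read_len, dtype=np.int64)
    seqs: list[str] = []
    for lo in range(0, n_reads, _CHUNK_READS):
        idx = starts[lo : lo + _CHUNK_READS, None] + offs[None, :]
        bases = gcodes[idx].astype(np.int8)
        s = site_rate[idx]
        u = rng.random(idx.shape)
        hit = u < s
        alt = site_alt[idx]
        fixed = hit & (alt >= 0)
        bases[fixed] = alt[fixed]
        rand_sub = (hit & (alt < 0)) | (~hit & (u < s + (1.0 - s) * base_error))
        if rand_sub.any():
            shift = rng.integers(1, 4, size=int(rand_sub.sum()), dtype=np.int8)
            bases[rand_sub] = (bases[rand_sub] + shift) % 4
        flat = bases.ravel()
        lut = np.frombuffer(BASES.encode(), dtype=np.uint8)
        byte_rows = lut[flat].tobytes()
        for r in range(idx.shape[0]):
            seqs.append(byte_rows[r * read_len : (r + 1) * read_len].decode("ascii"))
    return ReadSet(
        genome_id=genome.id,
        genome_len=L,
        read_len=read_len,
        starts=starts,
        seqs=seqs,
        reverse=reverse,
        params=params,
    )


def simulate_mutprofile_reads(
    genome: Genome,
    truth: TruthTable,
    arm: str,
    depth: float,
    read_len: int = DEFAULT_READ_LEN,
    seed: Optional[int] = None,
    dose_multiplier: float = 1.0,
    reverse_frac: float = 0.0,
) -> ReadSet:
    """Crosslink-profile reads for one arm of a test/control pair.

    In the ``test`` arm, crosslink sites gain their configured extra U->C
    rate (scaled by ``dose_multiplier``, the 4SU dose/time knob); fixed
    minority variants apply in both arms; uniform error applies everywhere.
    """
    if arm not in ("test", "control"):
        raise ValueError("arm must be 'test' or 'control'")
    truth.validate_against(genome)
    L = len(genome)
    site_rate = np.zeros(L)
    site_alt = np.full(L, -1, dtype=np.int8)
    for p, (alt, r) in truth.variant_sites.items():
        site_rate[p - 1] = r
        site_alt[p - 1] = BASE_INDEX[alt]
    if arm == "test":
        for p, r in truth.crosslink_sites.items():
            if site_rate[p - 1] > 0:
                raise ValueError(f"position {p} has both a variant and a crosslink site")
            site_rate[p - 1] = min(1.0, r * dose_multiplier)
            site_alt[p - 1] = BASE_INDEX["C"]
        for p, r in truth.dms_unpaired.items():
            if site_rate[p - 1] > 0:
                raise ValueError(f"position {p} has conflicting truth entries")
            site_rate[p - 1] = r
            site_alt[p - 1] = -1
    params = {
        "kind": "mutprofile",
        "arm": arm,
        "depth": depth,
        "read_len": read_len,
        "seed": seed,
        "dose_multiplier": dose_multiplier,
        "reverse_frac": reverse_frac,
        "base_error": truth.base_error,
        "n_crosslink_sites": len(truth.crosslink_sites),
        "n_variant_sites": len(truth.variant_sites),
        "genome_id": genome.id,
        "genome_len": L,
    }
    return _draw_reads(
        genome, site_rate, site_alt, truth.base_error, depth, read_len, seed,
        reverse_frac, params,
    )


def simulate_dms_reads(
    genome: Genome,
    structure: StructureModel,
    unpaired_rate: float,
    paired_rate: float,
    depth: float,
    seed: Optional[int] = None,
    arm: str = "test",
    base_error: float = 0.0,
    read_len: int = DEFAULT_READ_LEN,
) -> ReadSet:
    """Structure-probing reads: in the test (DMS+) arm, unpaired A/C positions
    mutate at ``unpaired_rate`` and paired A/C at ``paired_rate``, to a
    uniformly chosen non-reference base; the control arm carries only
    ``base_error``. G/T positions never receive the probing signal.
    """
    if not unpaired_rate > paired_rate >= 0:
        raise ValueError("need unpaired_rate > paired_rate >= 0")
    if arm not in ("test", "control"):
        raise ValueError("arm must be 'test' or 'control'")
    if len(structure) != len(genome):
        raise ValueError("structure/genome length mismatch")
    L = len(genome)
    site_rate = np.zeros(L)
    site_alt = np.full(L, -1, dtype=np.int8)
    if arm == "test":
        gcodes = genome.codes
        ac = (gcodes == BASE_INDEX["A"]) | (gcodes == BASE_INDEX["C"])
        unpaired = structure.pair == 0
        site_rate[ac & unpaired] = unpaired_rate
        site_rate[ac & ~unpaired] = paired_rate
    params = {
        "kind": "dms",
        "arm": arm,
        "depth": depth,
        "read_len": read_len,
        "seed": seed,
        "unpaired_rate": unpaired_rate,
        "paired_rate": paired_rate,
        "base_error": base_error,
        "genome_id": genome.id,
        "genome_len": L,
    }
    return _draw_reads(
        genome, site_rate, site_alt, base_error, depth, read_len, seed, 0.0, params
    )


def random_truth(
    genome: Genome,
    n_crosslink: int,
    crosslink_rate: float,
    n_variants: int = 0,
    variant_rate: float = 0.0,
    base_error: float = 0.001,
    seed: Optional[int] = None,
    margin: int = 0,
) -> TruthTable:
    """Draw a TruthTable with random U-position crosslink sites and (optionally)
    random both-arm minority variants at distinct U positions.

    ``margin`` excludes sites within that many nt of the genome ends (where
    uniform read starts give reduced coverage).
    """
    rng = np.random.default_rng(seed)
    u_pos = genome.u_positions
    u_pos = u_pos[(u_pos > margin) & (u_pos <= len(genome) - margin)]
    if len(u_pos) < n_crosslink + n_variants:
        raise ValueError("not enough eligible U positions")
    chosen = rng.choice(u_pos, size=n_crosslink + n_variants, replace=False)
    tt = TruthTable(base_error=base_error)
    for p in sorted(chosen[:n_crosslink]):
        tt.crosslink_sites[int(p)] = crosslink_rate
    for p in sorted(chosen[n_crosslink:]):
        tt.variant_sites[int(p)] = ("C", variant_rate)
    return tt
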