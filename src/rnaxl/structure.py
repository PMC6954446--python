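"""RNA secondary-structure bridging.

Strong single-strandedness signals become unpaired constraints for an
external thermodynamic folding engine (interfaced purely through files:
FASTA + CON out, CT back in). A self-contained maximum-base-pairing folder
(`toy_fold`) stands in for the engine so the constraint -> fold -> metrics
path is testable offline. Genomes are held in DNA alphabet; folding treats
T as U.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np

from rnaxl.mutsignal import ConsensusSignal, SignalProfile, sigma_cutoff
from rnaxl.pileup import Genome

#: allowed pairs, DNA alphabet (T == U): Watson-Crick plus GU wobble
CANONICAL_PAIRS = frozenset(
    [("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")]
)

DEFAULT_MIN_LOOP = 3


@dataclasses.dataclass(frozen=True)
class ConstraintSet:
    """Positions forced single-stranded during folding (1-based, ascending)."""

    genome_id: str
    unpaired_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        pos = tuple(int(p) for p in self.unpaired_positions)
        if any(p < 1 for p in pos):
            raise ValueError("positions are 1-based")
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("positions must be strictly ascending")
        object.__setattr__(self, "unpaired_positions", pos)

    def __len__(self) -> int:
        return len(self.unpaired_positions)

    def validate_against(self, genome: Genome) -> None:
        if self.unpaired_positions and self.unpaired_positions[-1] > len(genome):
            raise ValueError("constraint position beyond genome length")


@dataclasses.dataclass
class StructureModel:
    """Pairing map: ``pair[i]`` (1-based position i+1) is the partner position, 0 = unpaired."""

    genome_id: str
    pair: np.ndarray  # (L,) int64

    def __post_init__(self) -> None:
        self.pair = np.asarray(self.pair, dtype=np.int64)
        L = len(self.pair)
        for i, j in enumerate(self.pair, start=1):
            if j == 0:
                continue
            if not 1 <= j <= L:
                raise ValueError(f"position {i}: partner {j} out of range")
            if j == i:
                raise ValueError(f"position {i} pairs with itself")
            if self.pair[j - 1] != i:
                raise ValueError(f"pairing not involutive at position {i}")

    def __len__(self) -> int:
        return len(self.pair)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, StructureModel)
            and self.genome_id == other.genome_id
            and np.array_equal(self.pair, other.pair)
        )

    @property
    def paired_mask(self) -> np.ndarray:
        return self.pair != 0

    def is_paired(self, position: int) -> bool:
        return bool(self.pair[position - 1] != 0)

    def to_dotbracket(self) -> str:
        out = ["."] * len(self)
        for i, j in enumerate(self.pair, start=1):
            if j == 0:
                continue
            if j > i:
                inner = self.pair[i : j - 1]
                if ((inner != 0) & ((inner < i) | (inner > j))).any():
                    raise ValueError("structure contains pseudoknots; cannot emit dot-bracket")
                out[i - 1] = "("
                out[j - 1] = ")"
        return "".join(out)

    def to_ct(self, path: Union[str, Path], genome: Genome) -> None:
        if len(genome) != len(self):
            raise ValueError("genome/structure length mismatch")
        seq = genome.seq.replace("T", "U")
        with open(path, "w") as fh:
            fh.write(f"{len(self)} {self.genome_id}\n")
            for i in range(1, len(self) + 1):
                fh.write(
                    f"{i} {seq[i - 1]} {i - 1} {(i + 1) if i < len(self) else 0} "
                    f"{self.pair[i - 1]} {i}\n"
                )


# ---------------------------------------------------------------------------
# Constraint selection and the CON file dialect


def select_unpaired_constraints(
    dms: Union[ConsensusSignal, SignalProfile],
    rule: Union[str, Tuple[str, float]],
) -> ConstraintSet:
    """Pick positions with the strongest single-strandedness signal.

    ``rule`` is ``("sigma", k)`` / ``"sigma:k"`` (signal > mean + k*sd over all
    present signals) or ``("top", frac)`` / ``"top:frac"`` (highest
    ceil(frac * n) signals). Only positions passing the background filter
    (for a consensus profile: consistent positions) are eligible.
    """
    if isinstance(rule, str):
        name, _, arg = rule.partition(":")
        rule = (name, float(arg))
    name, arg = rule

    if isinstance(dms, ConsensusSignal):
        values = dms.mean_signal
        eligible = dms.consistent
    else:
        values = dms.signal
        eligible = dms.passed_background
    present = ~np.isnan(values)

    if name == "sigma":
        if present.sum() < 2:
            return ConstraintSet(dms.genome_id, ())
        cutoff = sigma_cutoff(values, arg)
        sel = present & eligible & (values > cutoff)
        positions = np.flatnonzero(sel) + 1
    elif name == "top":
        idx = np.flatnonzero(present & eligible)
        n_sel = int(np.ceil(arg * len(idx)))
        order = idx[np.argsort(-values[idx], kind="stable")]
        positions = np.sort(order[:n_sel]) + 1
    else:
        raise ValueError(f"unknown constraint rule {name!r}")
    return ConstraintSet(dms.genome_id, tuple(int(p) for p in positions))


# CON dialect sections, in required order; True = pair section ("-1 -1" terminator)
_CON_SECTIONS = (("DS", False), ("SS", False), ("Mod", False),
                 ("Pairs", True), ("FMN", False), ("Forbids", True))


def write_constraint_file(constraints: ConstraintSet, path: Union[str, Path]) -> None:
    """Emit the folding-constraint (CON) dialect with unpaired positions under SS."""
    with open(path, "w") as fh:
        for section, is_pair in _CON_SECTIONS:
            fh.write(f"{section}:\n")
            if section == "SS":
                for p in constraints.unpaired_positions:
                    fh.write(f"{p}\n")
            fh.write("-1 -1\n" if is_pair else "-1\n")


def read_constraint_file(path: Union[str, Path], genome_id: str = "") -> ConstraintSet:
    """Inverse of :func:`write_constraint_file` (SS section only)."""
    positions: list[int] = []
    section = None
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.endswith(":"):
            section = line[:-1]
            continue
        if line.split()[0] == "-1":
            continue
        if section == "SS":
            positions.append(int(line.split()[0]))
    return ConstraintSet(genome_id, tuple(sorted(positions)))


# ---------------------------------------------------------------------------
# Structure file parsing


def parse_dotbracket(text: str, genome_id: str = "") -> StructureModel:
    """Parse a nested dot-bracket string (optionally with >header / sequence lines)."""
    struct = None
    for line in text.strip().splitlines():
        line = line.strip()
        if not line or line.startswith(">"):
            continue
        if set(line) <= set("()."):
            struct = line
            break
    if struct is None:
        raise ValueError("no dot-bracket line found")
    pair = np.zeros(len(struct), dtype=np.int64)
    stack: list[int] = []
    for i, ch in enumerate(struct, start=1):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            pair[i - 1] = j
            pair[j - 1] = i
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return StructureModel(genome_id, pair)


def parse_ct(text: str, genome_id: str = "") -> StructureModel:
    """Parse a connectivity-table (CT) file; arbitrary listed pairs allowed."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError("empty CT file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise ValueError("malformed CT header") from exc
    if len(lines) < n + 1:
        raise ValueError(f"CT file truncated: header says {n} positions")
    pair = np.zeros(n, dtype=np.int64)
    for ln in lines[1 : n + 1]:
        fields = ln.split()
        if len(fields) < 6:
            raise ValueError(f"malformed CT row: {ln!r}")
        i, j = int(fields[0]), int(fields[4])
        if not 1 <= i <= n:
            raise ValueError(f"CT index {i} out of range")
        pair[i - 1] = j
    for i in range(1, n + 1):
        j = pair[i - 1]
        if j != 0 and (not 1 <= j <= n or pair[j - 1] != i):
            raise ValueError(f"non-involutive CT pairing at position {i}")
    return StructureModel(genome_id, pair)


def parse_structure(path: Union[str, Path], genome_id: str = "") -> StructureModel:
    """Parse a CT (.ct) or dot-bracket (.db/.dbn/other) structure file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".ct":
        return parse_ct(text, genome_id)
    return parse_dotbracket(text, genome_id)


# ---------------------------------------------------------------------------
# Structure metrics


def ds_fraction(s: StructureModel) -> float:
    """Fraction of positions that are base-paired."""
    if len(s) == 0:
        return 0.0
    return float(s.paired_mask.sum() / len(s))


def refold_difference(a: StructureModel, b: StructureModel) -> float:
    """Fraction of positions whose paired/unpaired *status* differs.

    Status-level: a position paired in both models counts as unchanged even
    when the partner differs.
    """
    if len(a) != len(b):
        raise ValueError("structures differ in length")
    if len(a) == 0:
        return 0.0
    return float((a.paired_mask != b.paired_mask).sum() / len(a))


# ---------------------------------------------------------------------------
# Self-contained maximum-pairing folder (Nussinov-style, constraint-aware)


def _can_pair(a: str, b: str) -> bool:
    return (a, b) in CANONICAL_PAIRS


def toy_fold(
    genome: Genome,
    constraints: Optional[ConstraintSet] = None,
    min_loop: int = DEFAULT_MIN_LOOP,
) -> StructureModel:
    """Maximum base-pair count nested structure with constrained positions unpaired.

    Pairs are Watson-Crick plus GU, with |i - j| > min_loop. Among co-optimal
    structures the traceback is deterministic: each 5' position pairs with the
    smallest admissible partner whenever pairing it preserves optimality.
    Not a thermodynamic model -- a stand-in for the external folding engine.
    """
    seq = genome.seq
    L = len(seq)
    blocked = np.zeros(L + 1, dtype=bool)
    if constraints is not None:
        constraints.validate_against(genome)
        for p in constraints.unpaired_positions:
            blocked[p] = True

    # N[i][j]: max pairs in 1-based inclusive interval [i, j]
    N = np.zeros((L + 2, L + 2), dtype=np.int64)
    for span in range(min_loop + 1, L):
        for i in range(1, L - span + 1):
            j = i + span
            best = N[i + 1, j]  # i unpaired
            if not blocked[i]:
                for k in range(i + min_loop + 1, j + 1):
                    if blocked[k] or not _can_pair(seq[i - 1], seq[k - 1]):
                        continue
                    cand = N[i + 1, k - 1] + N[k + 1, j] + 1
                    if cand > best:
                        best = cand
            N[i, j] = best

    pair = np.zeros(L, dtype=np.int64)
    stack = [(1, L)] if L else []
    while stack:
        i, j = stack.pop()
        if i >= j:
            continue
        target = N[i, j]
        if target == 0:
            continue
        paired = False
        if not blocked[i]:
            for k in range(i + min_loop + 1, j + 1):
                if blocked[k] or not _can_pair(seq[i - 1], seq[k - 1]):
                    continue
                if N[i + 1, k - 1] + N[k + 1, j] + 1 == target:
                    pair[i - 1] = k
                    pair[k - 1] = i
                    stack.append((i + 1, k - 1))
                    stack.append((k + 1, j))
                    paired = True
                    break
        if not paired:
            stack.append((i + 1, j))
    return StructureModel(genome.id, pair)
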