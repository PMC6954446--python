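"""Site-level analyses: structural context, dsRNA enrichment, clustering nulls."""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from rnaxl.structure import StructureModel


@dataclasses.dataclass(frozen=True)
class SiteSet:
    """Called sites on one genome: ascending unique 1-based positions, with
    per-site signal values and the sigma level used to call them."""

    genome_id: str
    positions: tuple[int, ...]
    signals: Optional[tuple[float, ...]] = None
    sigma_level: Optional[float] = None

    def __post_init__(self) -> None:
        pos = tuple(int(p) for p in self.positions)
        if any(p < 1 for p in pos):
            raise ValueError("positions are 1-based")
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("positions must be strictly ascending and unique")
        object.__setattr__(self, "positions", pos)
        if self.signals is not None:
            sig = tuple(float(s) for s in self.signals)
            if len(sig) != len(pos):
                raise ValueError("signals/positions length mismatch")
            object.__setattr__(self, "signals", sig)

    def __len__(self) -> int:
        return len(self.positions)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"position": self.positions})
        if self.signals is not None:
            df["signal"] = self.signals
        if self.sigma_level is not None:
            df["sigma_level"] = self.sigma_level
        return df

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_bed(self, path: Union[str, Path]) -> None:
        """BED6-ish output; BED is 0-based half-open so chromStart = position - 1."""
        with open(path, "w") as fh:
            for i, p in enumerate(self.positions):
                score = self.signals[i] if self.signals is not None else 0.0
                fh.write(f"{self.genome_id}\t{p - 1}\t{p}\tsite{i + 1}\t{score:g}\t+\n")


def classify_site_context(
    sites: SiteSet, structure: StructureModel, adjacency: int = 1
) -> list[str]:
    """Label each site ``ds`` (paired), ``ss_adjacent`` (unpaired but within
    ``adjacency`` nt of a paired position) or ``ss``.

    The adjacency window is clipped at the genome ends. With adjacency 0,
    ``ss_adjacent`` collapses into ``ss``.
    """
    if sites.genome_id and structure.genome_id and sites.genome_id != structure.genome_id:
        raise ValueError("genome mismatch between sites and structure")
    L = len(structure)
    labels = []
    paired = structure.paired_mask
    for p in sites.positions:
        if not 1 <= p <= L:
            raise ValueError(f"site {p} out of structure range 1..{L}")
        if paired[p - 1]:
            labels.append("ds")
            continue
        lo = max(1, p - adjacency)
        hi = min(L, p + adjacency)
        if paired[lo - 1 : hi].any():
            labels.append("ss_adjacent")
        else:
            labels.append("ss")
    return labels


def ds_enrichment_chisq(
    n_ds: int, n_total: int, expected_ds_frac: float
) -> Tuple[float, float]:
    """1-df goodness-of-fit chi-square of observed (ds, non-ds) site counts
    against the genome-wide expected ds fraction; no continuity correction.
    """
    if not 0 <= n_ds <= n_total:
        raise ValueError("need 0 <= n_ds <= n_total")
    if not 0 < expected_ds_frac < 1:
        raise ValueError("expected_ds_frac must be in (0, 1)")
    expected = np.array(
        [expected_ds_frac * n_total, (1 - expected_ds_frac) * n_total]
    )
    if (expected < 1).any():
        warnings.warn("chi-square expected cell below 1; statistic unreliable")
    observed = np.array([n_ds, n_total - n_ds])
    chi2, p = stats.chisquare(observed, f_exp=expected)
    return float(chi2), float(p)


def adjacent_spacing(sites: Union[SiteSet, Sequence[int]]) -> float:
    """Mean distance between consecutive sorted sites, in nt."""
    positions = sites.positions if isinstance(sites, SiteSet) else sorted(sites)
    if len(positions) < 2:
        raise ValueError("need at least 2 sites")
    diffs = np.diff(np.asarray(positions, dtype=float))
    return float(diffs.mean())


def null_spacing(
    genome_len: int,
    n_sites: int,
    mode: str = "analytic",
    uridine_positions: Optional[Sequence[int]] = None,
    reps: int = 1000,
    seed: Optional[int] = None,
) -> float:
    """Expected adjacent-site spacing for random sites.

    ``analytic``: genome_len / n_sites. ``monte_carlo``: mean adjacent
    spacing over ``reps`` seeded draws of ``n_sites`` positions sampled
    without replacement from ``uridine_positions``.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if mode == "analytic":
        return genome_len / n_sites
    if mode == "monte_carlo":
        if uridine_positions is None:
            raise ValueError("monte_carlo mode requires uridine_positions")
        if n_sites < 2:
            raise ValueError("monte_carlo spacing needs n_sites >= 2")
        pool = np.asarray(uridine_positions, dtype=np.int64)
        if len(pool) < n_sites:
            raise ValueError("fewer uridine positions than n_sites")
        rng = np.random.default_rng(seed)
        means = np.empty(reps)
        for r in range(reps):
            draw = np.sort(rng.choice(pool, size=n_sites, replace=False))
            means[r] = np.diff(draw).mean()
        return float(means.mean())
    raise ValueError(f"unknown mode {mode!r}")
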