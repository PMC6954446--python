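"""Paired test/control mutational signals.

The signal at a position is the fold change of its substitution rate between
a treated sample and its matched untreated control. Calling proceeds as
coverage mask -> fold change -> control-derived background filter ->
replicate consensus -> site selection; the statistics used by the reporting
layer (Pearson, Kolmogorov-Smirnov, t tests) live here too.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from rnaxl.pileup import Genome, RateProfile

DEFAULT_MIN_COVERAGE = 10_000
DEFAULT_BACKGROUND_TOP_FRAC = 0.05


@dataclasses.dataclass
class SignalProfile:
    """Per-position fold change (test rate / control rate) with audit trails.

    ``signal`` is NaN wherever either member of the pair is ABSENT.
    ``passed_background`` is only ever True where the signal is present.
    """

    genome_id: str
    event: str
    signal: np.ndarray  # (L,) float64, NaN = ABSENT
    passed_background: np.ndarray  # (L,) bool
    test_rate: np.ndarray
    control_rate: np.ndarray

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        self.passed_background = np.asarray(self.passed_background, dtype=bool)
        self.test_rate = np.asarray(self.test_rate, dtype=np.float64)
        self.control_rate = np.asarray(self.control_rate, dtype=np.float64)
        if self.passed_background[~self.present].any():
            raise ValueError("passed_background set at an absent position")

    def __len__(self) -> int:
        return len(self.signal)

    @property
    def present(self) -> np.ndarray:
        return ~np.isnan(self.signal)

    def to_frame(self, genome: Optional[Genome] = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "position": np.arange(1, len(self) + 1),
                "test_rate": self.test_rate,
                "control_rate": self.control_rate,
                "signal": self.signal,
                "passed_background": self.passed_background,
            }
        )
        if genome is not None:
            df.insert(1, "ref_base", list(genome.seq))
        return df

    def to_tsv(self, path: Union[str, Path], genome: Optional[Genome] = None) -> None:
        self.to_frame(genome).to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_tsv(cls, path: Union[str, Path], genome_id: str = "", event: str = "") -> "SignalProfile":
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
        return cls(
            genome_id=genome_id,
            event=event,
            signal=df["signal"].to_numpy(dtype=float),
            passed_background=df["passed_background"].fillna(False).to_numpy(dtype=bool),
            test_rate=df["test_rate"].to_numpy(dtype=float),
            control_rate=df["control_rate"].to_numpy(dtype=float),
        )


@dataclasses.dataclass
class ConsensusSignal:
    """Replicate signals after per-replicate background filtering.

    ``replicate_signals[k, i]`` is replicate k's signal at position i+1 if it
    passed that replicate's background filter, else NaN (vacant).
    ``consistent`` marks positions passing in every replicate; ``mean_signal``
    averages whatever replicates remain.
    """

    genome_id: str
    event: str
    replicate_signals: np.ndarray  # (k, L) float64
    mean_signal: np.ndarray  # (L,) float64, NaN where vacant
    consistent: np.ndarray  # (L,) bool

    def __post_init__(self) -> None:
        self.replicate_signals = np.asarray(self.replicate_signals, dtype=np.float64)
        self.mean_signal = np.asarray(self.mean_signal, dtype=np.float64)
        self.consistent = np.asarray(self.consistent, dtype=bool)

    def __len__(self) -> int:
        return self.replicate_signals.shape[1]

    @property
    def n_replicates(self) -> int:
        return self.replicate_signals.shape[0]

    @property
    def n_passing(self) -> np.ndarray:
        return (~np.isnan(self.replicate_signals)).sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"position": np.arange(1, len(self) + 1)})
        for k in range(self.n_replicates):
            df[f"signal_rep{k + 1}"] = self.replicate_signals[k]
        df["mean_signal"] = self.mean_signal
        df["n_passing"] = self.n_passing
        df["consistent"] = self.consistent
        return df

    def to_tsv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_tsv(cls, path: Union[str, Path], genome_id: str = "", event: str = "") -> "ConsensusSignal":
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
        rep_cols = [c for c in df.columns if c.startswith("signal_rep")]
        reps = df[rep_cols].to_numpy(dtype=float).T
        return cls(
            genome_id=genome_id,
            event=event,
            replicate_signals=reps,
            mean_signal=df["mean_signal"].to_numpy(dtype=float),
            consistent=df["consistent"].fillna(False).to_numpy(dtype=bool),
        )


def apply_coverage_mask(profile: RateProfile, min_cov: int = DEFAULT_MIN_COVERAGE) -> RateProfile:
    """Set positions with coverage < ``min_cov`` ABSENT (strict inequality)."""
    ok = profile.coverage >= min_cov
    rate = profile.rate.copy()
    rate[~ok] = np.nan
    return RateProfile(
        genome_id=profile.genome_id,
        event=profile.event,
        rate=rate,
        coverage=profile.coverage,
        coverage_ok=profile.coverage_ok & ok,
    )


def fold_change(test: RateProfile, control: RateProfile) -> SignalProfile:
    """signal = test_rate / max(control_rate, 1/control_coverage).

    The floor keeps fold change finite when the control observed zero events,
    calibrated to what one event at that control depth would have implied.
    Positions absent in either member are absent in the signal.
    """
    if test.genome_id != control.genome_id:
        raise ValueError("genome mismatch between test and control")
    if test.event != control.event:
        raise ValueError(f"event-class mismatch: {test.event!r} vs {control.event!r}")
    present = test.present & control.present
    signal = np.full(len(test), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        floor = np.where(control.coverage > 0, 1.0 / np.maximum(control.coverage, 1), np.nan)
        denom = np.maximum(control.rate, floor)
        signal[present] = test.rate[present] / denom[present]
    return SignalProfile(
        genome_id=test.genome_id,
        event=test.event,
        signal=signal,
        passed_background=np.zeros(len(test), dtype=bool),
        test_rate=test.rate,
        control_rate=control.rate,
    )


def background_threshold(
    control: Union[RateProfile, np.ndarray, Sequence[float]],
    top_frac: float = DEFAULT_BACKGROUND_TOP_FRAC,
) -> float:
    """Nearest-rank (1 - top_frac) percentile of the present control rates.

    Sorted ascending, the threshold is the value at 1-based rank
    ``ceil((1 - top_frac) * n)``.
    """
    if isinstance(control, RateProfile):
        values = control.present_values()
    else:
        values = np.asarray(control, dtype=float)
        values = values[~np.isnan(values)]
    n = len(values)
    if n == 0:
        raise ValueError("control has no present positions")
    rank = max(1, math.ceil((1.0 - top_frac) * n))
    return float(np.sort(values)[rank - 1])


def filter_background(signal: SignalProfile, threshold: float) -> SignalProfile:
    """Flag positions whose *test rate* is at or above the control-derived threshold.

    Positions below the threshold are indistinguishable from background
    fluctuation; the signal values are retained for audit but flagged.
    """
    passed = signal.present & (signal.test_rate >= threshold)
    return dataclasses.replace(signal, passed_background=passed)


def combine_replicates(signals: Sequence[SignalProfile]) -> ConsensusSignal:
    """Per-position consensus over background-filtered replicates.

    A replicate contributes its signal only where it passed its own background
    filter; the mean is over contributing replicates and a position is
    ``consistent`` when every replicate contributed.
    """
    if len(signals) < 2:
        raise ValueError("need at least 2 replicates")
    gid = signals[0].genome_id
    event = signals[0].event
    L = len(signals[0])
    for s in signals[1:]:
        if s.genome_id != gid:
            raise ValueError("genome mismatch across replicates")
        if s.event != event:
            raise ValueError("event mismatch across replicates")
        if len(s) != L:
            raise ValueError("length mismatch across replicates")
    reps = np.full((len(signals), L), np.nan)
    for k, s in enumerate(signals):
        reps[k, s.passed_background] = s.signal[s.passed_background]
    n_pass = (~np.isnan(reps)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(n_pass > 0, np.nansum(reps, axis=0) / np.maximum(n_pass, 1), np.nan)
    return ConsensusSignal(
        genome_id=gid,
        event=event,
        replicate_signals=reps,
        mean_signal=mean,
        consistent=n_pass == len(signals),
    )


def sigma_sites(values: Union[np.ndarray, Sequence[float]], k: float) -> np.ndarray:
    """1-based positions whose value exceeds mean + k * sd.

    Mean and sd (sample sd, ddof=1) are computed over all present (non-NaN)
    values; NaN positions are never selected.
    """
    values = np.asarray(values, dtype=float)
    present = ~np.isnan(values)
    if present.sum() < 2:
        raise ValueError("need at least 2 present values")
    mu = values[present].mean()
    sd = values[present].std(ddof=1)
    cutoff = mu + k * sd
    return np.flatnonzero(present & (values > cutoff)) + 1


def sigma_cutoff(values: Union[np.ndarray, Sequence[float]], k: float) -> float:
    values = np.asarray(values, dtype=float)
    vals = values[~np.isnan(values)]
    return float(vals.mean() + k * vals.std(ddof=1))


def top_sites(
    consensus: ConsensusSignal, n: int, require_consistent: bool = True
) -> list[int]:
    """1-based positions of the ``n`` highest mean signals.

    Ties are broken by ascending position. With fewer than ``n`` candidates
    all candidates are returned (a warning is logged).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    eligible = ~np.isnan(consensus.mean_signal)
    if require_consistent:
        eligible &= consensus.consistent
    idx = np.flatnonzero(eligible)
    if len(idx) < n:
        import logging

        logging.getLogger(__name__).warning(
            "only %d candidate sites for top-%d selection", len(idx), n
        )
    # stable sort on descending signal keeps ascending-position tie-break
    order = idx[np.argsort(-consensus.mean_signal[idx], kind="stable")]
    return [int(i) + 1 for i in order[:n]]


# ---------------------------------------------------------------------------
# Statistics


def replicate_correlation(a: SignalProfile, b: SignalProfile) -> float:
    """Pearson r over jointly present signal values; NaN if undefined."""
    joint = a.present & b.present
    if joint.sum() < 3:
        raise ValueError("need at least 3 jointly present positions")
    x = a.signal[joint]
    y = b.signal[joint]
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov: (D, asymptotic p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def t_test_two_sample(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Welch two-sample t test, two-sided. Zero variance with equal means -> (0, 1)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per sample")
    if np.std(a) == 0 and np.std(b) == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def t_test_one_sample(a: Sequence[float], popmean: float) -> Tuple[float, float]:
    """One-sample t test against a reference mean, two-sided."""
    a = np.asarray(a, dtype=float)
    if len(a) < 2:
        raise ValueError("need at least 2 values")
    if np.std(a) == 0 and a.mean() == popmean:
        return 0.0, 1.0
    res = stats.ttest_1samp(a, popmean)
    return float(res.statistic), float(res.pvalue)
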