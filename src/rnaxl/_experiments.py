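"""Self-contained benchmark experiments over the full pipeline.

Shared by the acceptance test suite and ``scripts/acceptance.py`` so both
measure the same computation: simulate paired read sets with ground truth,
run them through SAM files, pileup, fold change, background filtering and
replicate consensus, then score site calling against the truth.
"""

from __future__ import annotations

import itertools
import tempfile
from pathlib import Path
from typing import Optional

import numpy as np

from rnaxl import mutsignal, pileup, simdata


def crosslink_recovery(
    seed: int,
    length: int = 3000,
    n_sites: int = 20,
    crosslink_rate: float = 0.02,
    base_error: float = 0.001,
    depth: float = 20_000,
    n_replicates: int = 3,
    read_len: int = 150,
    n_variants: int = 2,
    variant_rate: float = 0.05,
    min_cov: int = 10_000,
    top_frac: float = 0.05,
    sigma_k: float = 1.0,
    workdir: Optional[Path] = None,
) -> dict:
    """End-to-end truth recovery on simulated triplicate test/control pairs.

    Reads are written to SAM and re-ingested through the pileup stage. A site
    is *called* when it is consistent (passed the per-replicate background
    filter in every replicate) and its coverage-masked mean signal exceeds
    mean + sigma_k * sd. Returns recall/precision against the injected
    crosslink sites, the replicate Pearson correlations, and whether any
    both-arm minority variant was called.
    """
    genome = simdata.make_genome(length, seed=seed)
    truth = simdata.random_truth(
        genome,
        n_crosslink=n_sites,
        crosslink_rate=crosslink_rate,
        n_variants=n_variants,
        variant_rate=variant_rate,
        base_error=base_error,
        seed=seed + 1,
        margin=read_len,
    )

    def _run(tmp: Path) -> dict:
        signals = []
        for rep in range(1, n_replicates + 1):
            prof = {}
            for arm_idx, arm in enumerate(("test", "control")):
                rs = simdata.simulate_mutprofile_reads(
                    genome, truth, arm=arm, depth=depth, read_len=read_len,
                    seed=seed + 1000 * rep + arm_idx,
                )
                sam = tmp / f"rep{rep}_{arm}.sam"
                rs.write_sam(sam)
                counts = pileup.build_base_counts(sam, genome)
                prof[arm] = mutsignal.apply_coverage_mask(
                    pileup.transition_profile(counts, genome, "T", "C"), min_cov
                )
            sig = mutsignal.fold_change(prof["test"], prof["control"])
            thr = mutsignal.background_threshold(prof["control"], top_frac)
            signals.append(mutsignal.filter_background(sig, thr))

        consensus = mutsignal.combine_replicates(signals)
        stacked = np.stack([s.signal for s in signals])
        n_present = (~np.isnan(stacked)).sum(axis=0)
        masked_mean = np.where(
            n_present > 0, np.nansum(stacked, axis=0) / np.maximum(n_present, 1), np.nan
        )
        sigma_pos = set(int(p) for p in mutsignal.sigma_sites(masked_mean, sigma_k))
        called = sorted(p for p in sigma_pos if consensus.consistent[p - 1])

        truth_set = set(truth.crosslink_sites)
        called_set = set(called)
        tp = len(called_set & truth_set)
        recall = tp / len(truth_set) if truth_set else float("nan")
        precision = tp / len(called_set) if called_set else float("nan")
        pearson = [
            mutsignal.replicate_correlation(a, b)
            for a, b in itertools.combinations(signals, 2)
        ]
        variant_called = sorted(called_set & set(truth.variant_sites))
        return {
            "recall": recall,
            "precision": precision,
            "n_called": len(called_set),
            "n_truth": len(truth_set),
            "called": called,
            "replicate_pearson": pearson,
            "min_pearson": min(pearson) if pearson else float("nan"),
            "variants_called": variant_called,
            "truth_sites": sorted(truth_set),
            "variant_sites": sorted(truth.variant_sites),
        }

    if workdir is not None:
        return _run(Path(workdir))
    with tempfile.TemporaryDirectory() as tmp:
        return _run(Path(tmp))
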