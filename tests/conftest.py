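import numpy as np
import pytest

from rnaxl import mutsignal, pileup, simdata


def make_sam(path, genome, records):
    """Write a minimal SAM file. records: (name, flag, pos1, cigar, seq)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        fh.write(f"@SQ\tSN:{genome.id}\tLN:{len(genome)}\n")
        for name, flag, pos, cigar, seq in records:
            qual = "F" * len(seq)
            fh.write(f"{name}\t{flag}\t{genome.id}\t{pos}\t60\t{cigar}\t*\t0\t0\t{seq}\t{qual}\n")
    return path


def rate_profile(genome_id, rates, coverage=None, event="T>C"):
    """RateProfile from a list of rates (None = absent)."""
    rates = np.array([np.nan if r is None else r for r in rates], dtype=float)
    if coverage is None:
        coverage = np.full(len(rates), 100_000, dtype=np.int64)
    else:
        coverage = np.asarray(coverage, dtype=np.int64)
    return pileup.RateProfile(
        genome_id=genome_id,
        event=event,
        rate=rates,
        coverage=coverage,
        coverage_ok=~np.isnan(rates),
    )


@pytest.fixture(scope="session")
def small_genome():
    return simdata.make_genome(400, seed=11, genome_id="g400")


@pytest.fixture(scope="session")
def small_truth(small_genome):
    return simdata.random_truth(
        small_genome, n_crosslink=6, crosslink_rate=0.03,
        n_variants=1, variant_rate=0.05, base_error=0.001, seed=12, margin=60,
    )


@pytest.fixture(scope="session")
def small_pair_counts(tmp_path_factory, small_genome, small_truth):
    """Moderate-depth simulated test/control pair, piled up once per session."""
    tmp = tmp_path_factory.mktemp("smallpair")
    out = {}
    for i, arm in enumerate(("test", "control")):
        rs = simdata.simulate_mutprofile_reads(
            small_genome, small_truth, arm=arm, depth=2000, read_len=60, seed=20 + i
        )
        sam = tmp / f"{arm}.sam"
        rs.write_sam(sam)
        out[arm] = pileup.build_base_counts(sam, small_genome)
    return out


@pytest.fixture(scope="session")
def small_pair_signal(small_genome, small_pair_counts):
    profs = {
        arm: mutsignal.apply_coverage_mask(
            pileup.transition_profile(c, small_genome, "T", "C"), min_cov=1000
        )
        for arm, c in small_pair_counts.items()
    }
    sig = mutsignal.fold_change(profs["test"], profs["control"])
    thr = mutsignal.background_threshold(profs["control"])
    return mutsignal.filter_background(sig, thr)
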