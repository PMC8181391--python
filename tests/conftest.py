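import numpy as np
import pytest

from atacatlas.simulate import SimulationConfig, simulate_atlas


def small_config(**overrides) -> SimulationConfig:
    """A fast desk-scale design: 3 tissues, 2 reps, 50k fragments/sample."""
    defaults = dict(
        n_tissues=3,
        n_shared_peaks=30,
        n_specific_peaks_per_tissue=15,
        peak_width=300,
        peak_spacing=2000,  # keeps specific peaks > 2 kb from any TSS
        genome_size=200_000,
        n_chromosomes=2,
        fragments_per_sample=50_000,
        specific_fold=8.0,
        seed=11,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_result():
    """One shared in-memory simulation (with genome) for read-only tests."""
    return simulate_atlas(small_config())


@pytest.fixture(scope="session")
def sim_dataset(tmp_path_factory):
    """One shared on-disk simulated dataset for file-based stages."""
    outdir = tmp_path_factory.mktemp("simdata")
    config = small_config(seed=23)
    result = simulate_atlas(config, outdir=outdir)
    return config, result, outdir


def brute_force_base_union(intervals):
    """Oracle: per-base union of intervals, re-extracted as runs."""
    bases: dict[str, set[int]] = {}
    for iv in intervals:
        bases.setdefault(iv.chrom, set()).update(range(iv.start, iv.end))
    runs = []
    for chrom in sorted(bases):
        pos = sorted(bases[chrom])
        start = prev = pos[0]
        for p in pos[1:]:
            if p != prev + 1:
                runs.append((chrom, start, prev + 1))
                start = p
            prev = p
        runs.append((chrom, start, prev + 1))
    return runs


def random_intervals(rng: np.random.Generator, n, chroms=("chrA", "chrB"),
                     max_pos=10_000, max_width=400):
    from atacatlas.intervals import GenomicInterval

    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, max_pos - max_width))
        width = int(rng.integers(1, max_width))
        out.append(GenomicInterval(chrom, start, start + width))
    return out
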