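"""The synthetic-data generator: determinism, closed-form expectations,
sampling behavior, and equality of the counts-only and file routes."""

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from atacatlas.atlas import build_standard_peaks, reproducible_peaks
from atacatlas.quantify import build_count_matrix
from atacatlas.simulate import (
    SHARED,
    ConfigurationError,
    SimulationConfig,
    counts_on_atlas,
    expected_count_profile,
    simulate_atlas,
)
from atacatlas.specificity import entropy_score

from conftest import small_config


def _hash_dir(path: Path) -> dict[str, str]:
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(path.iterdir())
    }


class TestConfigValidation:
    def test_genome_too_small(self):
        with pytest.raises(ConfigurationError, match="requested"):
            simulate_atlas(
                small_config(genome_size=5_000, n_chromosomes=1),
                include_genome=False,
            )

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"background_fraction": 1.0},
            {"specific_fold": 0.5},
            {"n_tissues": 0},
            {"fragment_length": 1000, "peak_width": 300},
        ],
    )
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ConfigurationError):
            small_config(**kwargs)


class TestDeterminism:
    def test_identical_seed_gives_identical_files(self, tmp_path):
        cfg = small_config(fragments_per_sample=2000, seed=5)
        simulate_atlas(cfg, outdir=tmp_path / "a")
        simulate_atlas(cfg, outdir=tmp_path / "b")
        assert _hash_dir(tmp_path / "a") == _hash_dir(tmp_path / "b")

    def test_seed_changes_output(self):
        r1 = simulate_atlas(small_config(seed=1), include_genome=False)
        r2 = simulate_atlas(small_config(seed=2), include_genome=False)
        assert not r1.counts.equals(r2.counts)

    def test_counts_independent_of_genome_synthesis(self):
        cfg = small_config(seed=4)
        with_g = simulate_atlas(cfg, include_genome=True)
        without_g = simulate_atlas(cfg, include_genome=False)
        pd.testing.assert_frame_equal(with_g.counts, without_g.counts)


class TestExpectedProfiles:
    def test_shared_peak_expectation_uniform(self, small_result):
        truth, cfg = small_result.truth, small_result.config
        pid = next(p.peak_id for p in truth.peaks if p.label == SHARED)
        exp = expected_count_profile(truth, pid, cfg)
        assert np.allclose(exp, exp.iloc[0])

    def test_specific_peak_home_fold(self, small_result):
        truth, cfg = small_result.truth, small_result.config
        peak = next(p for p in truth.peaks if p.label != SHARED)
        exp = expected_count_profile(truth, peak.peak_id, cfg)
        others = exp.drop(peak.label)
        assert np.allclose(exp[peak.label] / others, cfg.specific_fold)

    def test_unknown_peak_id(self, small_result):
        with pytest.raises(KeyError):
            expected_count_profile(
                small_result.truth, "nope", small_result.config
            )

    def test_fold_one_gives_maximal_entropy(self):
        cfg = small_config(specific_fold=1.0)
        res = simulate_atlas(cfg, include_genome=False)
        for p in res.truth.peaks[:10]:
            exp = expected_count_profile(res.truth, p.peak_id, cfg)
            _, h = entropy_score(exp.to_numpy())
            assert h == pytest.approx(np.log2(cfg.n_tissues), abs=1e-12)

    def test_planted_design_beats_body_threshold(self):
        # analytic check: fold >= 8 with >= 10 tissues puts specific peaks
        # below the 3-bit body-organ cutoff
        cfg = SimulationConfig()  # 10 tissues, fold 8
        w = np.ones(cfg.n_tissues)
        w[0] = cfg.specific_fold
        _, h = entropy_score(w)
        assert h < 3.0
        _, h_shared = entropy_score(np.ones(cfg.n_tissues))
        assert h_shared == pytest.approx(np.log2(cfg.n_tissues))

    def test_empirical_mean_matches_expectation(self):
        # Monte-Carlo over seeds: sample mean within 3 SE of the closed form
        # layout reshuffles per seed, so track each seed's own first
        # specific peak; its home-tissue expectation is seed-invariant
        cfg = small_config(fragments_per_sample=5000)
        exp_home = None
        draws = []
        for seed in range(200):
            res = simulate_atlas(small_config(
                fragments_per_sample=5000, seed=seed), include_genome=False)
            peak = next(p for p in res.truth.peaks if p.label != SHARED)
            if exp_home is None:
                exp_home = expected_count_profile(
                    res.truth, peak.peak_id, cfg
                )[peak.label]
            draws.append(res.counts.loc[peak.peak_id, f"{peak.label}_rep1"])
        draws = np.asarray(draws, dtype=float)
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - exp_home) <= 3 * se


class TestSampling:
    def test_zero_fragments_gives_zero_counts(self):
        res = simulate_atlas(
            small_config(fragments_per_sample=0), include_genome=False
        )
        assert (res.counts.to_numpy() == 0).all()
        assert (res.library_sizes == 0).all()

    def test_background_fraction_respected(self, small_result):
        cfg = small_result.config
        in_peaks = small_result.counts.sum(axis=0)
        frac = in_peaks / small_result.library_sizes
        # binomial tolerance: 5 sigma at n = fragments_per_sample
        sigma = np.sqrt(
            cfg.background_fraction * (1 - cfg.background_fraction)
            / cfg.fragments_per_sample
        )
        assert (abs(frac - (1 - cfg.background_fraction)) < 5 * sigma).all()

    def test_library_size_is_column_sum_plus_background(self, small_result):
        expected = (
            small_result.counts.sum(axis=0) + small_result.background_counts
        )
        pd.testing.assert_series_equal(small_result.library_sizes, expected)


class TestFileRoute:
    def test_fragment_files_reproduce_drawn_counts(self, tmp_path):
        # jitter-free so atlas peaks coincide with true peaks: the fragment
        # route must reproduce the multinomial draw exactly
        cfg = small_config(
            fragments_per_sample=3000, replicate_jitter=0.0,
            noise_peak_rate=0.0, seed=9,
        )
        res = simulate_atlas(cfg, outdir=tmp_path)
        per_tissue = {
            t: reproducible_peaks(
                res.replicate_peaks[(t, 1)], res.replicate_peaks[(t, 2)]
            )
            for t in cfg.tissues
        }
        atl = build_standard_peaks(per_tissue)
        cm = build_count_matrix(
            atl,
            {s: tmp_path / f"{s}.fragments.bed" for s in cfg.sample_ids},
        )
        fast_counts, fast_lib = counts_on_atlas(res, atl.peaks)
        assert cm.counts.to_numpy().tolist() == fast_counts.to_numpy().tolist()
        assert cm.library_sizes.tolist() == fast_lib.tolist()

    def test_emitted_files_exist(self, sim_dataset):
        cfg, _result, outdir = sim_dataset
        expected = ["genome.fa", "tss.bed", "truth.json", "samples.tsv",
                    "config.yaml", "motifs.jaspar"]
        for name in expected:
            assert (outdir / name).exists()
        for s in cfg.sample_ids:
            assert (outdir / f"{s}.fragments.bed").exists()
            assert (outdir / f"{s}.peaks.bed").exists()


class TestTruthStructure:
    def test_every_peak_has_one_label(self, small_result):
        cfg = small_result.config
        labels = [p.label for p in small_result.truth.peaks]
        assert len(labels) == cfg.n_true_peaks
        assert labels.count(SHARED) == cfg.n_shared_peaks
        for t in cfg.tissues:
            assert labels.count(t) == cfg.n_specific_peaks_per_tissue

    def test_shared_peaks_carry_tss_specific_do_not(self, small_result):
        from atacatlas.intervals import distance_to_nearest_tss

        truth = small_result.truth
        ivs = [p.interval for p in truth.peaks]
        dists = distance_to_nearest_tss(ivs, small_result.tss)
        for p, (d, _g) in zip(truth.peaks, dists):
            if p.label == SHARED:
                assert d == 0
            else:
                assert d is None or d > 2000

    def test_planted_motifs_land_in_home_specific_peaks(self, small_result):
        truth = small_result.truth
        by_id = {p.peak_id: p for p in truth.peaks}
        assert truth.motif_placements, "some motifs must be planted"
        for placement in truth.motif_placements:
            peak = by_id[placement["peak_id"]]
            assert truth.motif_targets[placement["motif_id"]] == peak.label
            assert peak.start <= placement["position"] <= (
                peak.end - small_result.config.motif_length
            )
            cons = truth.motif_consensi[placement["motif_id"]]
            planted = small_result.genome.sequences[peak.chrom][
                placement["position"]: placement["position"] + len(cons)
            ]
            # instances are sampled from the PWM: near but not always equal
            matches = sum(a == b for a, b in zip(planted, cons))
            assert matches >= len(cons) - 3
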