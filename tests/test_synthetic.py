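"""Determinism and statistical fidelity of the synthetic-data generators."""

import hashlib
import json
from pathlib import Path

import numpy as np
import pytest

from airway_epi.annotation import pwm_max_score, scan_pwm
from airway_epi.organoid import fis_table, read_swelling_csv
from airway_epi.simulate import (
    SimulationConfig,
    make_counts_direct,
    make_fragments,
    make_genome,
    make_pwm_and_plant,
    make_replicate_peaks,
    make_swelling,
    make_true_peaks,
    simulate_dataset,
)


def dir_hashes(d):
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(Path(d).iterdir())
        if p.is_file()
    }


class TestGenome:
    def test_identical_seed_identical_output(self, small_sim_config):
        a = make_genome(small_sim_config)
        b = make_genome(small_sim_config)
        assert a[0] == b[0]
        assert a[1] == b[1]
        assert a[2] == b[2]

    def test_zero_genes_rejected(self, small_sim_config):
        import dataclasses

        cfg = dataclasses.replace(small_sim_config, n_genes=0)
        with pytest.raises(ValueError):
            make_genome(cfg)

    def test_tss_min_spacing_respected(self, small_sim_config):
        _, tss, _ = make_genome(small_sim_config)
        by_chrom = {}
        for r in tss:
            by_chrom.setdefault(r.chrom, []).append(r.tss)
        for positions in by_chrom.values():
            positions.sort()
            assert np.all(np.diff(positions) >= small_sim_config.tss_min_spacing)

    def test_impossible_spacing_rejected(self):
        cfg = SimulationConfig(
            seed=0, chrom_sizes={"chr1": 50_000}, n_genes=50, tss_min_spacing=6_000
        )
        with pytest.raises(ValueError, match="spacing"):
            make_genome(cfg)


class TestReplicatePeaks:
    def test_full_reproducibility_zero_jitter_reproduces_truth(self, small_sim_config):
        import dataclasses

        cfg = dataclasses.replace(
            small_sim_config, reproducibility=1.0, boundary_jitter=0,
            noise_peaks_per_sample=0,
        )
        truth = make_true_peaks(cfg)
        reps = make_replicate_peaks(cfg, truth)
        expected = sorted(truth.peaks, key=lambda p: (p.chrom, p.start, p.end))
        for sample, peaks in reps.items():
            assert peaks == expected

    def test_no_noise_means_no_private_peaks(self, small_sim_config):
        import dataclasses

        cfg = dataclasses.replace(small_sim_config, noise_peaks_per_sample=0)
        truth = make_true_peaks(cfg)
        reps = make_replicate_peaks(cfg, truth)
        for sample, peaks in reps.items():
            assert len(peaks) == len(truth.replicate_presence[sample])

    def test_mean_support_within_binomial_ci(self):
        cfg = SimulationConfig(seed=9, reproducibility=0.6, noise_peaks_per_sample=0)
        truth = make_true_peaks(cfg)
        make_replicate_peaks(cfg, truth)
        n_samples = len(cfg.sample_ids)
        present = np.zeros((len(truth.peaks), n_samples), dtype=bool)
        for j, s in enumerate(cfg.sample_ids):
            present[truth.replicate_presence[s], j] = True
        rate = present.mean()
        n = present.size
        half_ci = 4 * np.sqrt(0.6 * 0.4 / n)
        assert abs(rate - 0.6) < half_ci


class TestCountsDirect:
    def test_poisson_limit_variance_matches_mean(self):
        cfg = SimulationConfig(
            seed=1, n_true_peaks=1, nb_dispersion=0.0, effect_fraction=0.0,
            groups={"nasal": 2, "bronchial": 2},
            size_factors={"nasal_1": 1, "nasal_2": 1, "bronchial_1": 1, "bronchial_2": 1},
        )
        draws = []
        for salt in range(2500):
            m, truth = make_counts_direct(cfg, salt=salt)
            draws.extend(m.counts.ravel().tolist())
        draws = np.array(draws)
        assert draws.var() / draws.mean() == pytest.approx(1.0, rel=0.1)

    def test_null_group_means_equal(self):
        cfg = SimulationConfig(seed=2, n_true_peaks=2000, effect_fraction=0.0)
        m, truth = make_counts_direct(cfg)
        sf = np.array([truth.size_factors[s] for s in m.sample_ids])
        q = m.counts / sf[None, :]
        groups = np.array([cfg.design[s] for s in m.sample_ids])
        ratio = q[:, groups == "nasal"].mean() / q[:, groups == "bronchial"].mean()
        assert ratio == pytest.approx(1.0, abs=0.02)

    def test_seed_reproducibility(self):
        cfg = SimulationConfig(seed=3, n_true_peaks=50)
        m1, _ = make_counts_direct(cfg)
        m2, _ = make_counts_direct(cfg)
        np.testing.assert_array_equal(m1.counts, m2.counts)


class TestFragments:
    def test_depth_scales_with_size_factor(self, small_sim_config):
        import dataclasses

        sf = {s: 1.0 for s in small_sim_config.sample_ids}
        sf["nasal_1"] = 2.0
        cfg = dataclasses.replace(small_sim_config, size_factors=sf, tss_fold=1.0)
        truth = make_true_peaks(cfg)
        frags = make_fragments(cfg, truth)
        n1 = len(frags["nasal_1"])
        others = [len(frags[s]) for s in cfg.sample_ids if s != "nasal_1"]
        mean_other = np.mean(others)
        assert n1 / mean_other == pytest.approx(2.0, rel=0.15)

    def test_group_effect_visible_in_counts(self, small_sim_config):
        """A 4-fold planted shift shows up in depth-normalized peak counts."""
        import dataclasses

        from airway_epi.consensus import ConsensusPeak
        from airway_epi.counts import count_fragments

        cfg = dataclasses.replace(
            small_sim_config, effect_fraction=0.2, effect_log2fc=2.0, tss_fold=1.0
        )
        truth = make_true_peaks(cfg)
        frags = make_fragments(cfg, truth)
        peaks = [
            ConsensusPeak(region=p, support={s: True for s in cfg.sample_ids})
            for p in truth.peaks
        ]
        m = count_fragments(peaks, frags)
        sf = np.array([truth.size_factors[s] for s in m.sample_ids])
        q = m.counts / sf[None, :]
        groups = np.array([cfg.design[s] for s in m.sample_ids])
        up = truth.peak_effects == 2.0
        ratio = q[np.ix_(up, groups == "nasal")].mean() / q[
            np.ix_(up, groups == "bronchial")
        ].mean()
        assert ratio == pytest.approx(4.0, rel=0.25)


class TestMotifPlanting:
    def test_full_plant_fraction_writes_consensus_everywhere(self, small_sim_config):
        import dataclasses

        cfg = dataclasses.replace(small_sim_config, plant_fraction=1.0)
        _, _, genome = make_genome(cfg)
        truth = make_true_peaks(cfg)
        pwms, genome = make_pwm_and_plant(cfg, truth, genome)
        cons = pwms[0].consensus
        fg = [i for i, e in enumerate(truth.peak_effects) if e > 0]
        assert set(truth.carrier_peaks) == set(fg)
        for i in truth.carrier_peaks:
            p = truth.peaks[i]
            mid = (p.start + p.end) // 2
            start = mid - len(cons) // 2
            assert genome[p.chrom][start : start + len(cons)] == cons

    def test_planted_consensus_recovered_by_scan(self, small_sim_config):
        truth = make_true_peaks(small_sim_config)
        _, _, genome = make_genome(small_sim_config)
        pwms, genome = make_pwm_and_plant(small_sim_config, truth, genome)
        target = pwms[0]
        thr = 0.8 * pwm_max_score(target)
        found = 0
        for i in truth.carrier_peaks:
            p = truth.peaks[i]
            mid = (p.start + p.end) // 2
            window = genome[p.chrom][mid - 100 : mid + 100]
            if scan_pwm(window, target, thr):
                found += 1
        assert found >= 0.95 * len(truth.carrier_peaks)


class TestSwelling:
    def test_zero_rate_zero_noise_auc_zero(self):
        cfg = SimulationConfig(
            seed=0, swelling_rates={"vehicle": 0.0}, swelling_noise_sd=0.0
        )
        df, _ = make_swelling(cfg)
        table = fis_table(
            read_swelling_csv_from_frame(df)
        )
        assert np.allclose(table["auc"], 0.0)

    def test_linear_rate_closed_form(self):
        cfg = SimulationConfig(
            seed=0, swelling_rates={"forskolin": 0.01}, swelling_noise_sd=0.0
        )
        df, _ = make_swelling(cfg)
        table = fis_table(read_swelling_csv_from_frame(df))
        assert np.allclose(table["auc"], 7200.0)
        final = table[table["t_min"] == 120.0]["percent_area"]
        assert np.allclose(final, 220.0)

    def test_noisy_auc_mean_near_closed_form(self):
        cfg = SimulationConfig(
            seed=4, swelling_rates={"forskolin": 0.01}, swelling_noise_sd=0.03,
            wells_per_condition=100,
        )
        df, _ = make_swelling(cfg)
        table = fis_table(read_swelling_csv_from_frame(df))
        aucs = table.groupby("well_id")["auc"].first()
        se = aucs.std() / np.sqrt(len(aucs))
        assert abs(aucs.mean() - 7200.0) < 4 * se + 50


def read_swelling_csv_from_frame(df):
    from airway_epi.organoid import SwellingSeries

    out = []
    for (well, cond), grp in df.groupby(["well_id", "condition"], sort=True):
        grp = grp.sort_values("t_min")
        out.append(
            SwellingSeries(well, cond, grp["t_min"].to_numpy(), grp["total_area"].to_numpy())
        )
    return out


class TestFullDataset:
    def test_byte_identical_reruns(self, small_sim_config, tmp_path):
        d1 = simulate_dataset(small_sim_config, tmp_path / "a")
        d2 = simulate_dataset(small_sim_config, tmp_path / "b")
        assert dir_hashes(d1) == dir_hashes(d2)

    def test_truth_json_consistent_with_files(self, small_sim_config, tmp_path):
        d = simulate_dataset(small_sim_config, tmp_path / "sim")
        truth = json.loads((d / "truth.json").read_text())
        assert len(truth["peaks"]) == len(truth["peak_effects"])
        assert set(truth["size_factors"]) == set(small_sim_config.sample_ids)
        assert truth["target_motif_id"] == "TARGET"
        for name in ["sample_sheet.tsv", "genome.fa", "tss.tsv", "chrom.sizes",
                     "pwms.json", "swelling.csv", "boxes.csv"]:
            assert (d / name).exists()
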