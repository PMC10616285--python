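"""Regulatory-domain rule vs brute force; PWM scanning; motif enrichment."""

import numpy as np
import pytest

from airway_epi.annotation import (
    build_regulatory_domains,
    assign_peaks_to_genes,
    motif_enrichment,
    pwm_max_score,
    scan_pwm,
)
from airway_epi.consensus import ConsensusPeak
from airway_epi.intervals import ChromSizes, GenomicInterval, PWM, TSSRecord


def brute_force_domains(tss, chrom_sizes, up=5000, down=1000, cap=1_000_000):
    """Direct restatement of the basal-plus-extension rule, O(n^2)."""
    basal = {}
    for r in tss:
        lo, hi = (r.tss - up, r.tss + down) if r.strand == "+" else (r.tss - down, r.tss + up)
        basal[r.gene_id] = (max(lo, 0), min(hi, chrom_sizes[r.chrom]), r.chrom)
    out = {}
    for r in tss:
        b_lo, b_hi, chrom = basal[r.gene_id]
        left, right = max(b_lo - cap, 0), min(b_hi + cap, chrom_sizes[chrom])
        for g, (o_lo, o_hi, o_chrom) in basal.items():
            if g == r.gene_id or o_chrom != chrom:
                continue
            if o_lo < b_lo:  # neighbour on the left limits leftward extension
                left = max(left, min(o_hi, b_lo))
            if o_hi > b_hi:
                right = min(right, max(o_lo, b_hi))
        out[r.gene_id] = ((b_lo, b_hi), (left, right))
    return out


def sharp_pwm(consensus_codes, motif_id="M"):
    mat = np.full((len(consensus_codes), 4), 0.01)
    for i, c in enumerate(consensus_codes):
        mat[i, c] = 0.97
    return PWM(motif_id, mat)


def make_peak(chrom, start, end):
    return ConsensusPeak(region=GenomicInterval(chrom, start, end), support={"s": True})


class TestRegulatoryDomains:
    SIZES = ChromSizes({"chr1": 5_000_000})

    def test_isolated_gene_full_extension(self):
        doms = build_regulatory_domains(
            [TSSRecord("g", "chr1", "+", 2_500_000)], self.SIZES
        )
        d = doms[0]
        assert (d.basal.start, d.basal.end) == (2_495_000, 2_501_000)
        assert (d.extended.start, d.extended.end) == (1_495_000, 3_501_000)

    def test_two_plus_genes_ten_kb_apart(self):
        tss = [
            TSSRecord("up", "chr1", "+", 1_000_000),
            TSSRecord("dn", "chr1", "+", 1_010_000),
        ]
        doms = {d.gene_id: d for d in build_regulatory_domains(tss, self.SIZES)}
        # upstream gene's rightward extension stops at the downstream basal start
        assert doms["up"].extended.end == 1_005_000
        # downstream gene's leftward extension stops at the upstream basal end
        assert doms["dn"].extended.start == 1_001_000

    def test_gene_at_chromosome_start_clipped(self):
        doms = build_regulatory_domains([TSSRecord("g", "chr1", "+", 2_000)], self.SIZES)
        assert doms[0].basal.start == 0
        assert doms[0].extended.start == 0

    def test_minus_strand_basal_mirrored(self):
        doms = build_regulatory_domains(
            [TSSRecord("g", "chr1", "-", 2_500_000)], self.SIZES
        )
        assert (doms[0].basal.start, doms[0].basal.end) == (2_499_000, 2_505_000)

    def test_tss_outside_chromosome_rejected(self):
        with pytest.raises(ValueError):
            build_regulatory_domains([TSSRecord("g", "chr1", "+", 6_000_000)], self.SIZES)

    def test_matches_brute_force_random_layouts(self, rng):
        sizes = ChromSizes({"chr1": 2_000_000, "chr2": 1_000_000})
        for _ in range(25):
            tss = []
            used = set()
            for i in range(int(rng.integers(2, 30))):
                chrom = "chr1" if rng.random() < 0.6 else "chr2"
                pos = int(rng.integers(0, sizes[chrom]))
                if (chrom, pos) in used:
                    continue
                used.add((chrom, pos))
                tss.append(TSSRecord(f"g{i}", chrom, "+-"[int(rng.integers(2))], pos))
            doms = build_regulatory_domains(tss, sizes, distal_cap=200_000)
            oracle = brute_force_domains(tss, sizes, cap=200_000)
            for d in doms:
                b, e = oracle[d.gene_id]
                assert (d.basal.start, d.basal.end) == b
                assert (d.extended.start, d.extended.end) == e

    def test_basal_domains_inviolate(self, rng):
        sizes = ChromSizes({"chr1": 500_000})
        positions = rng.choice(np.arange(1_000, 499_000), size=40, replace=False)
        tss = [
            TSSRecord(f"g{i}", "chr1", "+-"[int(rng.integers(2))], int(p))
            for i, p in enumerate(positions)
        ]
        for d in build_regulatory_domains(tss, sizes):
            assert d.extended.start <= d.basal.start
            assert d.extended.end >= d.basal.end


class TestAssignment:
    SIZES = ChromSizes({"chr1": 5_000_000, "chr9": 100_000})

    def test_peak_in_basal_domain(self):
        doms = build_regulatory_domains(
            [TSSRecord("g", "chr1", "+", 2_500_000)], self.SIZES
        )
        got = assign_peaks_to_genes([make_peak("chr1", 2_499_000, 2_499_500)], doms)
        assert got == {"chr1:2499000-2499500": ["g"]}

    def test_peak_in_overlapping_extended_domains(self):
        tss = [
            TSSRecord("a", "chr1", "+", 1_000_000),
            TSSRecord("b", "chr1", "+", 1_400_000),
        ]
        doms = build_regulatory_domains(tss, self.SIZES)
        # midway: inside a's rightward extension (stops at b's basal) and...
        peak = make_peak("chr1", 1_200_000, 1_200_300)
        got = assign_peaks_to_genes([peak], doms)
        assert got[peak.peak_id] == ["a", "b"]

    def test_geneless_chromosome_unassigned(self):
        doms = build_regulatory_domains(
            [TSSRecord("g", "chr1", "+", 2_500_000)], self.SIZES
        )
        got = assign_peaks_to_genes([make_peak("chr9", 0, 100)], doms)
        assert got == {"chr9:0-100": []}


class TestScanPWM:
    def test_consensus_self_match(self):
        pwm = sharp_pwm([0, 1, 2, 3, 0, 1])  # ACGTAC
        hits = scan_pwm("ACGTAC", pwm, threshold=pwm_max_score(pwm))
        assert [(h.position, h.strand) for h in hits] == [(0, "+")]

    def test_reverse_complement_hit_on_minus(self):
        pwm = sharp_pwm([0, 0, 1, 2, 3, 3])  # AACGTT is its own revcomp? no: AACGTT
        seq = "GGGAACGTTGGG"
        thr = pwm_max_score(pwm)
        fwd_hits = scan_pwm(seq, pwm, thr)
        assert any(h.strand == "+" and h.position == 3 for h in fwd_hits)
        pwm2 = sharp_pwm([0, 0, 0, 1, 2, 2])  # AAACGG; revcomp CCGTTT
        hits = scan_pwm("TTCCGTTTAA", pwm2, thr)
        assert [(h.position, h.strand) for h in hits] == [(2, "-")]

    def test_all_n_sequence_no_hits(self):
        pwm = sharp_pwm([0, 1, 2])
        assert scan_pwm("NNNNNNNN", pwm, threshold=-100.0) == []

    def test_masked_lowercase_treated_as_n(self):
        pwm = sharp_pwm([0, 1, 2, 2])  # ACGG, not palindromic
        assert scan_pwm("acgg", pwm, pwm_max_score(pwm), mask=True) == []
        hits = scan_pwm("acgg", pwm, pwm_max_score(pwm), mask=False)
        assert [(h.position, h.strand) for h in hits] == [(0, "+")]

    def test_pwm_longer_than_sequence(self):
        pwm = sharp_pwm([0, 1, 2, 3, 0])
        assert scan_pwm("ACG", pwm, threshold=-100) == []

    def test_revcomp_mirror_symmetry(self, rng):
        """Hits on the reverse-complemented sequence mirror exactly."""
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        seq = "".join(rng.choice(list("ACGT"), size=80))
        rc = "".join(comp[c] for c in reversed(seq))
        pwm = sharp_pwm(list(rng.integers(0, 4, size=6)))
        thr = 0.7 * pwm_max_score(pwm)
        fwd = scan_pwm(seq, pwm, thr)
        rev = scan_pwm(rc, pwm, thr)
        L = len(pwm)
        mirrored = sorted(
            (len(seq) - h.position - L, "+-"[h.strand == "+"]) for h in rev
        )
        assert sorted((h.position, h.strand) for h in fwd) == mirrored


class TestMotifEnrichment:
    def _scenario(self, seed, plant_fraction):
        rng = np.random.default_rng(seed)
        n_fg, n_bg, width = 50, 200, 400
        chrom_len = (n_fg + n_bg) * 1000 + 2000
        genome = {"chr1": "".join(rng.choice(list("ACGT"), size=chrom_len))}
        target = sharp_pwm(list(rng.integers(0, 4, size=8)), "TARGET")
        decoys = [
            sharp_pwm(list(rng.integers(0, 4, size=8)), f"D{i}") for i in range(9)
        ]
        peaks = [
            make_peak("chr1", 500 + i * 1000, 500 + i * 1000 + width)
            for i in range(n_fg + n_bg)
        ]
        fg, bg = peaks[:n_fg], peaks[n_fg:]
        seq = list(genome["chr1"])
        cons = target.consensus
        for p in fg:
            if rng.random() < plant_fraction:
                mid = (p.region.start + p.region.end) // 2 - len(cons) // 2
                seq[mid : mid + len(cons)] = list(cons)
        genome["chr1"] = "".join(seq)
        return fg, bg, genome, [target] + decoys

    def test_planted_motif_ranks_first(self):
        fg, bg, genome, pwms = self._scenario(seed=0, plant_fraction=0.8)
        res = motif_enrichment(fg, bg, genome, pwms)
        best = min(res, key=lambda r: (r.padj, r.p))
        assert best.motif_id == "TARGET"
        assert best.padj < 0.01

    def test_null_planting_no_calls(self):
        fg, bg, genome, pwms = self._scenario(seed=1, plant_fraction=0.0)
        res = motif_enrichment(fg, bg, genome, pwms)
        assert all(r.padj >= 0.1 for r in res)

    def test_zero_foreground_hits_large_p(self):
        fg, bg, genome, pwms = self._scenario(seed=2, plant_fraction=0.0)
        res = motif_enrichment(fg, bg, genome, pwms)
        for r in res:
            if r.fg_hits == 0:
                assert r.p >= 0.5

    def test_empty_sets_rejected(self):
        fg, bg, genome, pwms = self._scenario(seed=3, plant_fraction=0.0)
        with pytest.raises(ValueError):
            motif_enrichment([], bg, genome, pwms)
        with pytest.raises(ValueError):
            motif_enrichment(fg, [], genome, pwms)
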