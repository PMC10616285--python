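"""Seeded generators for every input the pipeline consumes.

The generators emulate the study design the pipeline was built for: two
groups of airway basal-cell ATAC-seq replicates (5 nasal vs 4 bronchial,
one bronchial sample having been dropped for quality), peak calls that
reproduce across replicates with some probability, negative-binomially
dispersed fragment counts with sample-specific depths and group-specific
accessibility shifts, TSS-proximal fragment enrichment, transcription-factor
motifs planted in peak sequences, and linear-kinetics organoid swelling with
multiplicative noise measured in quadruplicate wells.

Every generator is driven by a numpy Generator seeded from
SimulationConfig.seed, and each emits a machine-readable ground-truth record
alongside the data so recovery can be checked end to end.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .counts import CountMatrix
from .intervals import (
    ChromSizes,
    Fragment,
    GenomicInterval,
    PWM,
    TSSRecord,
    write_bed,
    write_chrom_sizes,
    write_fasta,
    write_fragments,
    write_pwms,
    write_tss_table,
)

BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the emulated design."""

    seed: int = 0
    chrom_sizes: Dict[str, int] = field(
        default_factory=lambda: {
            "chr1": 1_000_000,
            "chr2": 800_000,
            "chrY": 120_000,
            "chrM": 16_000,
        }
    )
    n_genes: int = 80
    tss_min_spacing: int = 6_000
    n_true_peaks: int = 300
    peak_width: Tuple[int, int] = (200, 400)
    peak_min_gap: int = 800
    groups: Dict[str, int] = field(default_factory=lambda: {"nasal": 5, "bronchial": 4})
    reproducibility: float = 0.85
    boundary_jitter: int = 20
    noise_peaks_per_sample: int = 15
    size_factors: Optional[Dict[str, float]] = None  # default: log-spread around 1
    base_depth: int = 60_000
    frag_len: int = 64
    peak_mean_count: float = 120.0
    nb_dispersion: float = 0.1
    effect_fraction: float = 0.10
    effect_log2fc: float = 2.0
    tss_fold: float = 8.0
    background_fraction: float = 0.35
    motif_length: int = 8
    n_decoy_motifs: int = 9
    plant_fraction: float = 0.8
    swelling_rates: Dict[str, float] = field(
        default_factory=lambda: {"forskolin": 0.01, "vehicle": 0.0}
    )
    swelling_noise_sd: float = 0.03
    wells_per_condition: int = 4
    organoids_per_well: int = 30

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, salt))

    @property
    def sample_ids(self) -> List[str]:
        return [
            f"{g}_{i + 1}" for g, n in self.groups.items() for i in range(n)
        ]

    @property
    def design(self) -> Dict[str, str]:
        return {
            f"{g}_{i + 1}": g for g, n in self.groups.items() for i in range(n)
        }


@dataclass
class GroundTruth:
    peaks: List[GenomicInterval]
    peak_effects: np.ndarray  # per-peak log2FC (second group vs first)
    peak_base_means: np.ndarray
    size_factors: Dict[str, float]
    replicate_presence: Dict[str, List[int]]  # sample -> indices of true peaks present
    target_motif_id: Optional[str] = None
    carrier_peaks: List[int] = field(default_factory=list)
    swelling_rates: Dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        data = {
            "peaks": [[p.chrom, p.start, p.end] for p in self.peaks],
            "peak_effects": np.asarray(self.peak_effects).tolist(),
            "peak_base_means": np.asarray(self.peak_base_means).tolist(),
            "size_factors": self.size_factors,
            "replicate_presence": self.replicate_presence,
            "target_motif_id": self.target_motif_id,
            "carrier_peaks": list(self.carrier_peaks),
            "swelling_rates": self.swelling_rates,
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)


# ---------------------------------------------------------------------------
# Genome, genes, peaks


def make_genome(
    config: SimulationConfig,
) -> Tuple[ChromSizes, List[TSSRecord], Dict[str, str]]:
    """Chromosome sizes, TSS annotation with minimum spacing, and iid FASTA."""
    if config.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = config.rng(1)
    sizes = ChromSizes(dict(config.chrom_sizes))
    autosomes = {c: l for c, l in sizes.items() if c not in ("chrY", "chrM")}

    genome = {
        chrom: "".join(BASES[rng.integers(0, 4, size=length)])
        for chrom, length in sizes.items()
    }

    margin = 6_000  # keep full QC windows on-chromosome
    total = sum(autosomes.values())
    tss: List[TSSRecord] = []
    gene_idx = 0
    for chrom, length in autosomes.items():
        n_here = max(1, round(config.n_genes * length / total))
        usable = length - 2 * margin
        if usable < (n_here - 1) * config.tss_min_spacing:
            raise ValueError(f"cannot place {n_here} genes on {chrom} with spacing")
        # spaced placement: sorted draws on the slack then spread by min spacing
        slack = usable - (n_here - 1) * config.tss_min_spacing
        offsets = np.sort(rng.integers(0, slack + 1, size=n_here))
        positions = margin + offsets + np.arange(n_here) * config.tss_min_spacing
        strands = rng.choice(["+", "-"], size=n_here)
        for pos, strand in zip(positions, strands):
            tss.append(TSSRecord(f"gene{gene_idx:04d}", chrom, str(strand), int(pos)))
            gene_idx += 1
    return sizes, tss, genome


def make_true_peaks(config: SimulationConfig) -> GroundTruth:
    """Non-overlapping true peak universe with planted group effects.

    A configured fraction of peaks carries a true accessibility shift of
    +/- effect_log2fc (second group over first, balanced directions); the
    rest are null. Base mean counts are drawn log-uniform around
    peak_mean_count. A few peaks land on chrY/chrM to exercise filtering.
    """
    rng = config.rng(2)
    sizes = ChromSizes(dict(config.chrom_sizes))
    autosomes = {c: l for c, l in sizes.items() if c not in ("chrY", "chrM")}
    total = sum(autosomes.values())

    peaks: List[GenomicInterval] = []
    for chrom, length in autosomes.items():
        n_here = max(1, round(config.n_true_peaks * length / total))
        w_lo, w_hi = config.peak_width
        widths = rng.integers(w_lo, w_hi + 1, size=n_here)
        pitch = widths + config.peak_min_gap
        need = int(pitch.sum())
        if need > length - 2_000:
            raise ValueError(f"cannot fit {n_here} peaks on {chrom}")
        slack = length - 2_000 - need
        offsets = np.sort(rng.integers(0, slack + 1, size=n_here))
        starts = 1_000 + offsets + np.concatenate([[0], np.cumsum(pitch)[:-1]])
        for s, w in zip(starts, widths):
            peaks.append(GenomicInterval(chrom, int(s), int(s + w)))
    # decoy peaks on excluded chromosomes
    for chrom in ("chrY", "chrM"):
        if chrom in sizes and sizes[chrom] > 3_000:
            s = int(rng.integers(500, sizes[chrom] - 1_000))
            peaks.append(GenomicInterval(chrom, s, s + 300))

    n = len(peaks)
    effects = np.zeros(n)
    autosomal = [i for i, p in enumerate(peaks) if p.chrom in autosomes]
    n_eff = int(round(config.effect_fraction * len(autosomal)))
    chosen = rng.choice(autosomal, size=n_eff, replace=False)
    signs = np.where(np.arange(n_eff) % 2 == 0, 1.0, -1.0)
    effects[chosen] = signs * config.effect_log2fc

    base = np.exp(
        rng.uniform(
            np.log(config.peak_mean_count / 2), np.log(config.peak_mean_count * 2), size=n
        )
    )

    if config.size_factors is not None:
        sf = dict(config.size_factors)
    else:
        raw = np.exp(rng.uniform(-0.4, 0.4, size=len(config.sample_ids)))
        raw /= np.exp(np.mean(np.log(raw)))
        sf = dict(zip(config.sample_ids, raw.tolist()))

    return GroundTruth(
        peaks=peaks,
        peak_effects=effects,
        peak_base_means=base,
        size_factors=sf,
        replicate_presence={},
        swelling_rates=dict(config.swelling_rates),
    )


def make_replicate_peaks(
    config: SimulationConfig, truth: GroundTruth
) -> Dict[str, List[GenomicInterval]]:
    """Per-sample peak calls: Bernoulli presence, boundary jitter, noise peaks."""
    rng = config.rng(3)
    sizes = ChromSizes(dict(config.chrom_sizes))
    out: Dict[str, List[GenomicInterval]] = {}
    for sample in config.sample_ids:
        present = rng.random(len(truth.peaks)) < config.reproducibility
        truth.replicate_presence[sample] = [int(i) for i in np.flatnonzero(present)]
        peaks: List[GenomicInterval] = []
        for i in np.flatnonzero(present):
            p = truth.peaks[i]
            j = config.boundary_jitter
            if j > 0:
                ds = int(rng.integers(-j, j + 1))
                de = int(rng.integers(-j, j + 1))
            else:
                ds = de = 0
            s = max(0, p.start + ds)
            e = min(sizes[p.chrom], max(s + 50, p.end + de))
            peaks.append(GenomicInterval(p.chrom, s, e))
        autos = [c for c in sizes if c not in ("chrY", "chrM")]
        lengths = np.array([sizes[c] for c in autos], dtype=float)
        for _ in range(config.noise_peaks_per_sample):
            chrom = autos[int(rng.choice(len(autos), p=lengths / lengths.sum()))]
            s = int(rng.integers(0, sizes[chrom] - 400))
            peaks.append(GenomicInterval(chrom, s, s + int(rng.integers(150, 350))))
        peaks.sort(key=lambda p: (p.chrom, p.start, p.end))
        out[sample] = peaks
    return out


# ---------------------------------------------------------------------------
# Fragments and counts


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mean, dispersion alpha) via gamma-Poisson; Poisson when alpha ~ 0."""
    mean = np.asarray(mean, dtype=float)
    if alpha < 1e-8:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mean)
    return rng.poisson(lam)


def make_fragments(
    config: SimulationConfig, truth: GroundTruth
) -> Dict[str, List[Fragment]]:
    """Per-sample fragments: uniform background + NB peak counts + TSS pileup.

    Peak-concentrated fragments have their midpoints inside the peak, with
    per-(peak, sample) counts NB-distributed around
    s_j * base_mean_i * 2^(effect_i * x_j). The TSS component adds flat
    excess coverage over [-80, +80) around every TSS so that the expected
    enrichment ratio equals tss_fold.
    """
    sizes = ChromSizes(dict(config.chrom_sizes))
    _, tss, _ = make_genome(config)
    design = config.design
    groups = sorted(set(design.values()))
    frag_len = config.frag_len

    out: Dict[str, List[Fragment]] = {}
    for j, sample in enumerate(config.sample_ids):
        rng = config.rng(100 + j)
        sf = truth.size_factors[sample]
        x = 1.0 if design[sample] == groups[1] else 0.0
        frags: List[Fragment] = []

        # background, uniform over autosomes (plus a pinch on chrY/chrM)
        n_bg = rng.poisson(config.background_fraction * config.base_depth * sf)
        chroms = list(sizes)
        lengths = np.array([sizes[c] for c in chroms], dtype=float)
        picks = rng.choice(len(chroms), size=n_bg, p=lengths / lengths.sum())
        for c_idx in picks:
            chrom = chroms[c_idx]
            s = int(rng.integers(0, sizes[chrom] - frag_len))
            frags.append(Fragment(chrom, s, s + frag_len, sample))

        # peak-concentrated
        means = sf * truth.peak_base_means * np.exp2(truth.peak_effects * x)
        counts = _nb_draw(rng, means, config.nb_dispersion)
        for i, p in enumerate(truth.peaks):
            k = int(counts[i])
            if k == 0:
                continue
            mids = rng.integers(p.start, p.end, size=k)
            for m in mids:
                s = max(0, int(m) - frag_len // 2)
                e = min(sizes[p.chrom], s + frag_len)
                frags.append(Fragment(p.chrom, s, e, sample))

        # TSS-concentrated: flat excess over [-80, +80) at fold tss_fold
        if config.tss_fold > 1.0 and tss:
            genome_len = float(lengths.sum())
            bg_density = n_bg * frag_len / genome_len
            span = 160 + frag_len  # starts in [tss-80-L, tss+80) give flat cover
            per_tss = (config.tss_fold - 1.0) * bg_density * span / frag_len
            for rec in tss:
                k = rng.poisson(per_tss)
                if k == 0:
                    continue
                starts = rng.integers(rec.tss - 80 - frag_len, rec.tss + 80, size=k)
                for s in starts:
                    s = max(0, int(s))
                    e = min(sizes[rec.chrom], s + frag_len)
                    if e > s:
                        frags.append(Fragment(rec.chrom, s, e, sample))

        frags.sort(key=lambda f: (f.chrom, f.start, f.end))
        out[sample] = frags
    return out


def make_tss_fragments(
    n_fragments: int,
    tss: Sequence[TSSRecord],
    chrom_sizes: ChromSizes,
    fold: float,
    frag_len: int = 64,
    seed: int = 0,
    sample_id: str = "sim",
) -> List[Fragment]:
    """Fragments whose expected TSS-enrichment ratio equals `fold`.

    Background starts are uniform over the genome; the planted component has
    starts uniform over [tss - 80 - frag_len, tss + 80), which yields flat
    excess coverage across the central +/- 80 bp window. With fold = 1 the
    output is purely uniform.
    """
    rng = np.random.default_rng(seed)
    chroms = list(chrom_sizes)
    lengths = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    genome_len = float(lengths.sum())
    span = 160 + frag_len

    # split the budget so that planted/background densities give the fold
    weight_per_tss = span * (fold - 1.0) / genome_len
    planted_share = len(tss) * weight_per_tss / (1.0 + len(tss) * weight_per_tss)
    n_planted = rng.binomial(n_fragments, planted_share) if fold > 1 else 0
    n_bg = n_fragments - n_planted

    frags: List[Fragment] = []
    picks = rng.choice(len(chroms), size=n_bg, p=lengths / lengths.sum())
    for c_idx in picks:
        chrom = chroms[c_idx]
        s = int(rng.integers(0, chrom_sizes[chrom] - frag_len))
        frags.append(Fragment(chrom, s, s + frag_len, sample_id))
    if n_planted:
        which = rng.integers(0, len(tss), size=n_planted)
        for t_idx in which:
            rec = tss[t_idx]
            s = int(rng.integers(rec.tss - 80 - frag_len, rec.tss + 80))
            s = max(0, s)
            e = min(chrom_sizes[rec.chrom], s + frag_len)
            if e > s:
                frags.append(Fragment(rec.chrom, s, e, sample_id))
    return frags


def make_count_truth(config: SimulationConfig) -> GroundTruth:
    """Truth for fragment-free count simulations: peaks on a virtual axis.

    Used when only the count model matters (dispersion/test calibration);
    peak coordinates are synthetic and not bound by the FASTA genome.
    """
    rng = config.rng(2)
    n = config.n_true_peaks
    peaks = [
        GenomicInterval("chrSim", i * 1_000, i * 1_000 + 300) for i in range(n)
    ]
    effects = np.zeros(n)
    n_eff = int(round(config.effect_fraction * n))
    chosen = rng.choice(n, size=n_eff, replace=False)
    signs = np.where(np.arange(n_eff) % 2 == 0, 1.0, -1.0)
    effects[chosen] = signs * config.effect_log2fc
    base = np.exp(
        rng.uniform(
            np.log(config.peak_mean_count / 2), np.log(config.peak_mean_count * 2), size=n
        )
    )
    if config.size_factors is not None:
        sf = dict(config.size_factors)
    else:
        raw = np.exp(rng.uniform(-0.4, 0.4, size=len(config.sample_ids)))
        raw /= np.exp(np.mean(np.log(raw)))
        sf = dict(zip(config.sample_ids, raw.tolist()))
    return GroundTruth(
        peaks=peaks,
        peak_effects=effects,
        peak_base_means=base,
        size_factors=sf,
        replicate_presence={},
    )


def make_counts_direct(
    config: SimulationConfig, truth: Optional[GroundTruth] = None, salt: int = 4
) -> Tuple[CountMatrix, GroundTruth]:
    """Fragments-free count matrix: counts ~ NB(s_j * q_i * 2^(e_i * x_j), alpha)."""
    if truth is None:
        truth = make_count_truth(config)
    rng = config.rng(salt)
    design = config.design
    groups = sorted(set(design.values()))
    samples = config.sample_ids
    x = np.array([1.0 if design[s] == groups[1] else 0.0 for s in samples])
    sf = np.array([truth.size_factors[s] for s in samples])

    mean = (
        sf[None, :]
        * truth.peak_base_means[:, None]
        * np.exp2(truth.peak_effects[:, None] * x[None, :])
    )
    counts = _nb_draw(rng, mean, config.nb_dispersion)
    peak_ids = [f"{p.chrom}:{p.start}-{p.end}" for p in truth.peaks]
    return CountMatrix(peak_ids, samples, counts), truth


# ---------------------------------------------------------------------------
# Motifs


def _random_sharp_pwm(rng: np.random.Generator, motif_id: str, length: int) -> PWM:
    consensus = rng.integers(0, 4, size=length)
    matrix = np.full((length, 4), 0.01)
    matrix[np.arange(length), consensus] = 0.97
    return PWM(motif_id=motif_id, matrix=matrix)


def make_pwm_and_plant(
    config: SimulationConfig,
    truth: GroundTruth,
    genome: Dict[str, str],
    carrier_peaks: Optional[Sequence[int]] = None,
) -> Tuple[List[PWM], Dict[str, str]]:
    """A sharp target PWM planted into carrier peak centers, plus decoys.

    Carriers default to a plant_fraction sample of the peaks with positive
    group effect. Returns the PWM library (target first) and the modified
    genome; truth.carrier_peaks / target_motif_id are filled in.
    """
    rng = config.rng(5)
    target = _random_sharp_pwm(rng, "TARGET", config.motif_length)
    decoys = [
        _random_sharp_pwm(rng, f"DECOY{i + 1:02d}", config.motif_length)
        for i in range(config.n_decoy_motifs)
    ]

    if carrier_peaks is None:
        fg = [i for i, e in enumerate(truth.peak_effects) if e > 0]
        n_carry = int(round(config.plant_fraction * len(fg)))
        carrier_peaks = sorted(rng.choice(fg, size=n_carry, replace=False).tolist())

    seqs = {c: list(s) for c, s in genome.items()}
    consensus = target.consensus
    for i in carrier_peaks:
        p = truth.peaks[i]
        mid = (p.start + p.end) // 2
        start = mid - len(consensus) // 2
        seqs[p.chrom][start : start + len(consensus)] = list(consensus)
    truth.target_motif_id = target.motif_id
    truth.carrier_peaks = [int(i) for i in carrier_peaks]
    return [target] + decoys, {c: "".join(s) for c, s in seqs.items()}


# ---------------------------------------------------------------------------
# Organoids


def make_swelling(config: SimulationConfig) -> Tuple["pd.DataFrame", GroundTruth]:
    """Linear-kinetics FIS curves with multiplicative noise, quadruplicate wells.

    area(t) = A0 * (1 + r * t) * (1 + eps_t), eps ~ N(0, sd), on the 0..120
    min grid in 15-min steps. With sd = 0 the downstream AUC is exactly
    720000 * r %*min.
    """
    import pandas as pd

    rng = config.rng(6)
    t = np.arange(0.0, 121.0, 15.0)
    rows = []
    for cond, rate in config.swelling_rates.items():
        for w in range(config.wells_per_condition):
            a0 = float(rng.uniform(5_000, 20_000))
            noise = 1.0 + rng.normal(0.0, config.swelling_noise_sd, size=len(t))
            area = a0 * (1.0 + rate * t) * noise
            area = np.maximum(area, 1e-6)
            for tt, aa in zip(t, area):
                rows.append(
                    {
                        "well_id": f"{cond}_w{w + 1}",
                        "condition": cond,
                        "t_min": tt,
                        "total_area": aa,
                    }
                )
    truth = GroundTruth(
        peaks=[],
        peak_effects=np.array([]),
        peak_base_means=np.array([]),
        size_factors={},
        replicate_presence={},
        swelling_rates=dict(config.swelling_rates),
    )
    return pd.DataFrame(rows), truth


def make_boxes(config: SimulationConfig) -> "pd.DataFrame":
    """OrgaQuant-style bounding boxes: lognormal sizes, near-square boxes."""
    import pandas as pd

    rng = config.rng(7)
    rows = []
    for cond in config.swelling_rates:
        for w in range(config.wells_per_condition):
            n = config.organoids_per_well
            diam = rng.lognormal(mean=np.log(60.0), sigma=0.4, size=n)
            aspect = np.exp(rng.normal(0.0, 0.1, size=n))
            for d, a in zip(diam, aspect):
                rows.append(
                    {
                        "well_id": f"{cond}_w{w + 1}",
                        "x": float(rng.uniform(0, 2_000)),
                        "y": float(rng.uniform(0, 2_000)),
                        "width": float(d * a),
                        "height": float(d / a),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full dataset emission


def simulate_dataset(config: SimulationConfig, outdir) -> Path:
    """Write every pipeline input plus ground truth under `outdir`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    sizes, tss, genome = make_genome(config)
    truth = make_true_peaks(config)
    rep_peaks = make_replicate_peaks(config, truth)
    fragments = make_fragments(config, truth)
    pwms, genome = make_pwm_and_plant(config, truth, genome)
    swelling, _ = make_swelling(config)
    boxes = make_boxes(config)

    write_chrom_sizes(sizes, outdir / "chrom.sizes")
    write_tss_table(tss, outdir / "tss.tsv")
    write_fasta(genome, outdir / "genome.fa")
    write_pwms(pwms, outdir / "pwms.json")

    with open(outdir / "sample_sheet.tsv", "w") as fh:
        fh.write("sample_id\tgroup\tdonor_id\tpeaks_bed\tfragments_bed\n")
        design = config.design
        for i, sample in enumerate(config.sample_ids):
            peaks_bed = f"peaks_{sample}.bed"
            frags_bed = f"fragments_{sample}.bed"
            write_bed(rep_peaks[sample], outdir / peaks_bed)
            write_fragments(fragments[sample], outdir / frags_bed)
            fh.write(
                f"{sample}\t{design[sample]}\tdonor{i % 5 + 1}\t{peaks_bed}\t{frags_bed}\n"
            )

    swelling.to_csv(outdir / "swelling.csv", index=False)
    boxes.to_csv(outdir / "boxes.csv", index=False)
    truth.to_json(outdir / "truth.json")
    with open(outdir / "sim_config.json", "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=1, default=str)
    return outdir
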