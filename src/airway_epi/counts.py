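"""Fragment counting at consensus peaks and anchored size-factor normalization.

Counting assigns each fragment by its midpoint, so a fragment is counted at
most once even for adjacent peaks. Size factors follow the median-of-ratios
recipe, but computed only on the *universal* peak set (regions reproducible
in both groups) and then applied to all peaks: open chromatin differs
between the two tissues at many regions, and anchoring the factors on
regions accessible everywhere keeps genuine group differences from being
absorbed into the depth correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set

import numpy as np

from .consensus import ConsensusPeak
from .intervals import Fragment

logger = logging.getLogger(__name__)


@dataclass
class CountMatrix:
    peak_ids: List[str]
    sample_ids: List[str]
    counts: np.ndarray  # (n_peaks, n_samples) integer
    peak_meta: List[ConsensusPeak] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.peak_ids), len(self.sample_ids)):
            raise ValueError("counts shape inconsistent with id lists")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


@dataclass
class SizeFactors:
    factors: Dict[str, float]
    anchor_set: List[str]

    def __post_init__(self) -> None:
        for s, f in self.factors.items():
            if not f > 0:
                raise ValueError(f"non-positive size factor for sample {s}")

    def as_array(self, sample_ids: Sequence[str]) -> np.ndarray:
        missing = [s for s in sample_ids if s not in self.factors]
        if missing:
            raise KeyError(f"no size factor for samples: {missing}")
        return np.array([self.factors[s] for s in sample_ids])


def count_fragments(
    peaks: Sequence[ConsensusPeak],
    fragments_by_sample: Dict[str, Sequence[Fragment]],
) -> CountMatrix:
    """Fragments-in-peaks matrix: midpoint-in-region, half-open boundaries.

    A fragment whose midpoint equals a peak start is counted; one at the peak
    end is not. Peaks are assumed pairwise non-overlapping (consensus output).
    """
    sample_ids = list(fragments_by_sample)
    n_peaks, n_samples = len(peaks), len(sample_ids)
    counts = np.zeros((n_peaks, n_samples), dtype=np.int64)

    by_chrom: Dict[str, List[tuple]] = {}
    for idx, peak in enumerate(peaks):
        by_chrom.setdefault(peak.region.chrom, []).append(
            (peak.region.start, peak.region.end, idx)
        )
    chrom_arrays = {}
    for chrom, entries in by_chrom.items():
        entries.sort()
        starts = np.array([e[0] for e in entries], dtype=np.int64)
        ends = np.array([e[1] for e in entries], dtype=np.int64)
        idxs = np.array([e[2] for e in entries], dtype=np.int64)
        chrom_arrays[chrom] = (starts, ends, idxs)

    for j, sample in enumerate(sample_ids):
        frs = fragments_by_sample[sample]
        mids_by_chrom: Dict[str, List[int]] = {}
        for fr in frs:
            mids_by_chrom.setdefault(fr.chrom, []).append(fr.midpoint)
        for chrom, mids in mids_by_chrom.items():
            if chrom not in chrom_arrays:
                continue
            starts, ends, idxs = chrom_arrays[chrom]
            mids_arr = np.asarray(mids, dtype=np.int64)
            pos = np.searchsorted(starts, mids_arr, side="right") - 1
            valid = pos >= 0
            inside = np.zeros_like(valid)
            inside[valid] = mids_arr[valid] < ends[pos[valid]]
            hit_peaks = idxs[pos[inside]]
            np.add.at(counts[:, j], hit_peaks, 1)

    peak_ids = [p.peak_id for p in peaks]
    return CountMatrix(peak_ids, sample_ids, counts, list(peaks))


def anchored_size_factors(matrix: CountMatrix, anchor: Set[str]) -> SizeFactors:
    """Median-of-ratios size factors computed on the anchor (universal) peaks.

    Anchor peaks with a zero count in any sample are dropped (standard
    median-of-ratios zero handling). Factors are re-centred to geometric
    mean 1 and apply to *all* peaks during normalization.
    """
    if not anchor:
        raise ValueError("anchor peak set is empty")
    unknown = anchor - set(matrix.peak_ids)
    if unknown:
        raise ValueError(f"anchor peaks not in matrix: {sorted(unknown)[:5]}")
    idx = [i for i, pid in enumerate(matrix.peak_ids) if pid in anchor]
    sub = matrix.counts[idx, :].astype(float)

    zero_col = np.all(sub == 0, axis=0)
    if np.any(zero_col):
        bad = [matrix.sample_ids[j] for j in np.flatnonzero(zero_col)]
        raise ValueError(f"samples with all-zero anchor counts: {bad}")

    nonzero_rows = np.all(sub > 0, axis=1)
    dropped = int(np.sum(~nonzero_rows))
    if dropped:
        logger.info("anchored_size_factors: dropped %d anchor peaks with zeros", dropped)
    usable = sub[nonzero_rows, :]
    if usable.shape[0] == 0:
        raise ValueError("no anchor peak has nonzero counts in every sample")

    log_geomean = np.mean(np.log(usable), axis=1)
    log_ratios = np.log(usable) - log_geomean[:, None]
    log_factors = np.median(log_ratios, axis=0)
    log_factors -= log_factors.mean()  # geometric mean 1
    factors = np.exp(log_factors)
    return SizeFactors(
        factors=dict(zip(matrix.sample_ids, factors.tolist())),
        anchor_set=[matrix.peak_ids[i] for i in idx],
    )


def median_of_ratios(matrix: CountMatrix) -> SizeFactors:
    """Standard (all-peak) median-of-ratios; the unanchored comparator."""
    return anchored_size_factors(matrix, set(matrix.peak_ids))


def normalize(matrix: CountMatrix, factors: SizeFactors) -> np.ndarray:
    """normalized[i, j] = counts[i, j] / factor[j]."""
    f = factors.as_array(matrix.sample_ids)
    return matrix.counts / f[None, :]
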