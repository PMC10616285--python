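"""Consensus peak construction across biological replicates.

Replicate peak calls are merged transitively (any >=1 bp overlap chains
regions together) into non-overlapping union regions; each region records
which samples contributed a peak. A region is *reproducible* within a group
when at least `min_support` replicates of that group contributed (the study
design uses 3 of 4 bronchial and 3 of 5 nasal replicates), and *universal*
when it is reproducible in both groups. Universal peaks later anchor the
count normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from .intervals import GenomicInterval


class ConsensusStateError(RuntimeError):
    """Raised when universal peaks are requested before group reproducibility."""


@dataclass
class ReplicatePeakSet:
    sample_id: str
    group: str
    donor_id: str
    peaks: List[GenomicInterval]


@dataclass
class ConsensusPeak:
    region: GenomicInterval
    support: Dict[str, bool]
    group_reproducible: Dict[str, bool] = field(default_factory=dict)
    universal: bool = False

    @property
    def peak_id(self) -> str:
        return f"{self.region.chrom}:{self.region.start}-{self.region.end}"

    def support_count(self, samples: Optional[Sequence[str]] = None) -> int:
        if samples is None:
            return sum(self.support.values())
        return sum(self.support.get(s, False) for s in samples)


def merge_intervals(sets: Sequence[ReplicatePeakSet]) -> List[ConsensusPeak]:
    """Merge transitively overlapping replicate peaks into consensus regions.

    Output regions are pairwise non-overlapping, sorted by (chrom, start),
    and each records per-sample presence (>= 1 contributing peak).
    """
    if not sets:
        raise ValueError("need at least one replicate peak set")
    all_samples = [s.sample_id for s in sets]
    tagged = [
        (p.chrom, p.start, p.end, s.sample_id) for s in sets for p in s.peaks
    ]
    tagged.sort(key=lambda t: (t[0], t[1], t[2]))

    consensus: List[ConsensusPeak] = []
    cur_chrom: Optional[str] = None
    cur_start = cur_end = 0
    cur_samples: set = set()

    def _flush() -> None:
        if cur_chrom is None:
            return
        consensus.append(
            ConsensusPeak(
                region=GenomicInterval(cur_chrom, cur_start, cur_end),
                support={s: (s in cur_samples) for s in all_samples},
            )
        )

    for chrom, start, end, sample in tagged:
        # strict < : abutting half-open intervals do not share a bp
        if chrom == cur_chrom and start < cur_end:
            cur_end = max(cur_end, end)
            cur_samples.add(sample)
        else:
            _flush()
            cur_chrom, cur_start, cur_end = chrom, start, end
            cur_samples = {sample}
    _flush()
    return consensus


def reproducible_peaks(
    consensus: Sequence[ConsensusPeak],
    group: str,
    group_samples: Dict[str, List[str]],
    min_support: int = 3,
) -> List[ConsensusPeak]:
    """Regions supported by >= min_support replicates of `group`.

    Sets group_reproducible[group] on every input region and returns the
    passing subset. Default min_support of 3 matches the 3/4 and 3/5 rules.
    """
    if group not in group_samples:
        raise KeyError(f"unknown group {group!r}")
    samples = group_samples[group]
    if not (1 <= min_support <= len(samples)):
        raise ValueError(
            f"min_support {min_support} outside [1, {len(samples)}] for {group}"
        )
    kept: List[ConsensusPeak] = []
    for peak in consensus:
        ok = peak.support_count(samples) >= min_support
        peak.group_reproducible[group] = ok
        if ok:
            kept.append(peak)
    return kept


def universal_peaks(
    consensus: Sequence[ConsensusPeak],
    groups: Optional[Sequence[str]] = None,
    strict_all_samples: bool = False,
) -> List[ConsensusPeak]:
    """Regions reproducible in every group; marks universal=True.

    With strict_all_samples, a region must additionally be supported by
    literally every sample in the experiment.
    """
    out: List[ConsensusPeak] = []
    for peak in consensus:
        if groups is None:
            checked = list(peak.group_reproducible)
        else:
            checked = list(groups)
        if not checked:
            raise ConsensusStateError(
                "group reproducibility not computed before universal_peaks"
            )
        for g in checked:
            if g not in peak.group_reproducible:
                raise ConsensusStateError(
                    f"group {g!r} reproducibility not computed for {peak.peak_id}"
                )
        ok = all(peak.group_reproducible[g] for g in checked)
        if ok and strict_all_samples:
            ok = all(peak.support.values())
        peak.universal = ok
        if ok:
            out.append(peak)
    return out


def analysis_peak_universe(
    consensus: Sequence[ConsensusPeak], groups: Sequence[str]
) -> List[ConsensusPeak]:
    """Union over groups of group-reproducible regions (the downstream universe)."""
    return [
        p
        for p in consensus
        if any(p.group_reproducible.get(g, False) for g in groups)
    ]
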