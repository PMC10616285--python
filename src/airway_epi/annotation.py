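"""Peak-to-gene assignment and known-motif enrichment.

Gene assignment follows the "basal plus extension" regulatory-domain rule:
each gene owns a strand-aware basal domain (5 kb upstream, 1 kb downstream
of its TSS) which is extended outward to the nearer of a distance cap
(1,000 kb) or the flanking gene's basal domain; basal domains are never
truncated by neighbours. A peak is assigned to every gene whose extended
domain it overlaps.

Motif enrichment is a deliberately simple known-motif test: each peak is
represented by its central window (default 200 bp, masked bases treated as
N), scanned on both strands with log-odds PWM scores, and per-motif
peak-level hit counts are compared between foreground and background with a
one-sided hypergeometric test plus BH correction. This is not a
reimplementation of a de novo motif finder.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import stats

from .consensus import ConsensusPeak
from .differential import adjust_bh
from .intervals import ChromSizes, GenomicInterval, PWM, TSSRecord

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class RegulatoryDomain:
    gene_id: str
    basal: GenomicInterval
    extended: GenomicInterval


@dataclass
class MotifEnrichmentResult:
    motif_id: str
    fg_hits: int
    fg_total: int
    bg_hits: int
    bg_total: int
    p: float
    padj: float = float("nan")


def build_regulatory_domains(
    tss: Sequence[TSSRecord],
    chrom_sizes: ChromSizes,
    proximal_up: int = 5000,
    proximal_down: int = 1000,
    distal_cap: int = 1_000_000,
) -> List[RegulatoryDomain]:
    """Basal-plus-extension domains for every gene.

    Basal: [tss - proximal_up, tss + proximal_down) on the + strand, mirrored
    on the - strand, clipped to the chromosome. Extension pushes each basal
    edge outward to the nearer of `distal_cap` bp from that edge or the
    nearest flanking basal-domain edge; a gene's own basal domain is
    inviolate even when neighbouring basal domains overlap it.
    """
    basal: Dict[str, GenomicInterval] = {}
    for rec in tss:
        if rec.chrom not in chrom_sizes:
            raise ValueError(f"gene {rec.gene_id}: unknown chromosome {rec.chrom}")
        clen = chrom_sizes[rec.chrom]
        if rec.tss >= clen:
            raise ValueError(f"gene {rec.gene_id}: TSS {rec.tss} outside {rec.chrom}")
        if rec.strand == "+":
            lo, hi = rec.tss - proximal_up, rec.tss + proximal_down
        else:
            lo, hi = rec.tss - proximal_down, rec.tss + proximal_up
        basal[rec.gene_id] = GenomicInterval(
            rec.chrom, max(lo, 0), min(hi, clen), name=rec.gene_id
        )

    by_chrom: Dict[str, List[str]] = {}
    for rec in tss:
        by_chrom.setdefault(rec.chrom, []).append(rec.gene_id)

    domains: List[RegulatoryDomain] = []
    for rec in tss:
        b = basal[rec.gene_id]
        clen = chrom_sizes[rec.chrom]
        neighbours = [basal[g] for g in by_chrom[rec.chrom] if g != rec.gene_id]

        left_edges = [o.end for o in neighbours if o.start < b.start]
        left_limit = min(b.start, max(left_edges)) if left_edges else 0
        ext_start = max(b.start - distal_cap, 0, left_limit)

        right_edges = [o.start for o in neighbours if o.end > b.end]
        right_limit = max(b.end, min(right_edges)) if right_edges else clen
        ext_end = min(b.end + distal_cap, clen, right_limit)

        domains.append(
            RegulatoryDomain(
                gene_id=rec.gene_id,
                basal=b,
                extended=GenomicInterval(rec.chrom, ext_start, ext_end, name=rec.gene_id),
            )
        )
    return domains


def assign_peaks_to_genes(
    peaks: Sequence[ConsensusPeak], domains: Sequence[RegulatoryDomain]
) -> Dict[str, List[str]]:
    """peak_id -> gene_ids whose extended domain the peak overlaps (>= 1 bp)."""
    by_chrom: Dict[str, List[RegulatoryDomain]] = {}
    for d in domains:
        by_chrom.setdefault(d.extended.chrom, []).append(d)
    assignment: Dict[str, List[str]] = {}
    for peak in peaks:
        r = peak.region
        hits = [
            d.gene_id
            for d in by_chrom.get(r.chrom, [])
            if r.start < d.extended.end and d.extended.start < r.end
        ]
        assignment[peak.peak_id] = sorted(hits)
    return assignment


def _encode(sequence: str, mask: bool = True) -> np.ndarray:
    """Sequence -> integer codes; N (and lowercase when mask=True) -> 4."""
    out = np.full(len(sequence), 4, dtype=np.int8)
    for i, ch in enumerate(sequence):
        if ch.islower():
            if mask:
                continue
            ch = ch.upper()
        idx = _BASE_INDEX.get(ch)
        if idx is not None:
            out[i] = idx
    return out


def pwm_log_odds(pwm: PWM, pseudo: float = 1e-3) -> np.ndarray:
    """(L, 5) log2-odds matrix; column 4 (N/masked) scores -inf."""
    probs = (pwm.matrix + pseudo) / (1.0 + 4 * pseudo)
    lo = np.log2(probs / pwm.background[None, :])
    return np.hstack([lo, np.full((lo.shape[0], 1), -np.inf)])


def pwm_max_score(pwm: PWM, pseudo: float = 1e-3) -> float:
    return float(pwm_log_odds(pwm, pseudo)[:, :4].max(axis=1).sum())


@dataclass
class PWMHit:
    position: int  # 0-based start of the match window on the forward strand
    strand: str
    score: float


def scan_pwm(
    sequence: str,
    pwm: PWM,
    threshold: float,
    mask: bool = True,
) -> List[PWMHit]:
    """Log-odds scan of both strands; windows containing N score -inf.

    Returns hits with score >= threshold, each located by the forward-strand
    start of its L-bp window.
    """
    L = len(pwm)
    if L > len(sequence):
        return []
    codes = _encode(sequence, mask=mask)
    lo = pwm_log_odds(pwm)
    n_pos = len(sequence) - L + 1

    # reverse-complement scan == scanning with the reversed, complemented PWM
    rc_lo = lo[::-1, [3, 2, 1, 0, 4]]

    hits: List[PWMHit] = []
    idx = np.arange(L)
    windows = codes[np.arange(n_pos)[:, None] + idx[None, :]]
    fwd = lo[idx[None, :], windows].sum(axis=1)
    rev = rc_lo[idx[None, :], windows].sum(axis=1)
    for pos in np.flatnonzero(fwd >= threshold):
        hits.append(PWMHit(int(pos), "+", float(fwd[pos])))
    for pos in np.flatnonzero(rev >= threshold):
        hits.append(PWMHit(int(pos), "-", float(rev[pos])))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def peak_center_sequence(
    region: GenomicInterval, genome: Dict[str, str], window: int = 200
) -> str:
    """Central `window` bp of a peak (clipped to the chromosome)."""
    seq = genome[region.chrom]
    mid = (region.start + region.end) // 2
    lo = max(mid - window // 2, 0)
    hi = min(lo + window, len(seq))
    return seq[lo:hi]


def motif_enrichment(
    fg_peaks: Sequence[ConsensusPeak],
    bg_peaks: Sequence[ConsensusPeak],
    genome: Dict[str, str],
    pwms: Sequence[PWM],
    window: int = 200,
    mask: bool = True,
    threshold_fraction: float = 0.8,
) -> List[MotifEnrichmentResult]:
    """Hypergeometric known-motif enrichment of foreground vs background peaks.

    Each peak contributes its central `window` bp; a peak is a hit for a
    motif when the scan finds >= 1 match at a threshold of
    `threshold_fraction` x the motif's maximum log-odds score. The one-sided
    p is the hypergeometric tail of drawing fg_hits hits in fg_total draws
    from the pooled fg+bg population; padj is BH across motifs.
    """
    if not fg_peaks or not bg_peaks:
        raise ValueError("foreground and background peak sets must be non-empty")
    fg_seqs = [peak_center_sequence(p.region, genome, window) for p in fg_peaks]
    bg_seqs = [peak_center_sequence(p.region, genome, window) for p in bg_peaks]

    results: List[MotifEnrichmentResult] = []
    for pwm in pwms:
        thr = threshold_fraction * pwm_max_score(pwm)
        fg_hits = sum(1 for s in fg_seqs if scan_pwm(s, pwm, thr, mask))
        bg_hits = sum(1 for s in bg_seqs if scan_pwm(s, pwm, thr, mask))
        M = len(fg_seqs) + len(bg_seqs)
        K = fg_hits + bg_hits
        N = len(fg_seqs)
        p = float(stats.hypergeom.sf(fg_hits - 1, M, K, N))
        results.append(
            MotifEnrichmentResult(
                motif_id=pwm.motif_id,
                fg_hits=fg_hits,
                fg_total=len(fg_seqs),
                bg_hits=bg_hits,
                bg_total=len(bg_seqs),
                p=min(p, 1.0),
            )
        )
    padj = adjust_bh([r.p for r in results])
    for r, a in zip(results, padj):
        r.padj = float(a)
    return results
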