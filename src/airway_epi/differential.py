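"""Negative-binomial differential accessibility between two sample groups.

Per peak, counts are modelled as NB(mean = s_j * exp(b0 + b1 * x_j), alpha)
with x_j the group indicator and s_j the anchored size factor. Dispersion is
a per-peak method-of-moments estimate (no empirical-Bayes shrinkage); b1 is
fitted by iteratively reweighted least squares on the log link, vectorized
across peaks, and tested with a Wald statistic referred to a Student t with
n_samples - 2 degrees of freedom. The t reference (rather than the normal
limit) absorbs the extra variability of the plug-in dispersion at the
handful of replicates typical of these designs and keeps the raw-p type-I
error near nominal. Significance uses the study's thresholds:
|log2 fold change| > 1 and Benjamini-Hochberg adjusted p < 0.1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .counts import CountMatrix, SizeFactors

ALPHA_FLOOR = 1e-8
IRLS_TOL = 1e-8
IRLS_MAX_ITER = 100
_ETA_CLIP = 30.0  # keeps exp() finite for separated groups

LN2 = math.log(2.0)


@dataclass
class DispersionEstimate:
    peak_id: str
    alpha: float
    method: str  # "per-peak" | "common"


@dataclass
class DifferentialResult:
    peak_id: str
    baseMean: float
    log2FC: float
    se: float
    p: float  # NaN when untestable (all-zero peak, non-convergence)
    padj: float = float("nan")
    significant: bool = False
    direction: Optional[str] = None
    converged: bool = True


def _group_design(
    sample_ids: Sequence[str], design: Dict[str, str]
) -> Tuple[np.ndarray, str, str]:
    """Indicator vector for the second group; groups ordered alphabetically."""
    groups = sorted(set(design.values()))
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    group_a, group_b = groups
    x = np.array([1.0 if design[s] == group_b else 0.0 for s in sample_ids])
    for g in groups:
        if sum(design[s] == g for s in sample_ids) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    return x, group_a, group_b


def estimate_dispersion(
    matrix: CountMatrix,
    factors: SizeFactors,
    design: Dict[str, str],
    method: str = "per-peak",
) -> List[DispersionEstimate]:
    """Method-of-moments NB dispersion from within-group variability.

    On normalized counts q = y/s, Var(q) = mu * E[1/s] + alpha * mu^2 within
    a group; the excess of the pooled within-group variance over the Poisson
    part is solved for alpha and floored at 1e-8. `method="common"` replaces
    every estimate with a 20%-trimmed mean of the per-peak values.
    """
    s = factors.as_array(matrix.sample_ids)
    x, group_a, group_b = _group_design(matrix.sample_ids, design)
    q = matrix.counts / s[None, :]

    num = np.zeros(q.shape[0])
    den = np.zeros(q.shape[0])
    for g_mask in (x == 0, x == 1):
        n_g = int(g_mask.sum())
        qg = q[:, g_mask]
        m = qg.mean(axis=1)
        v = qg.var(axis=1, ddof=1)
        xi = float(np.mean(1.0 / s[g_mask]))  # Poisson part of Var(y/s)
        num += (n_g - 1) * (v - m * xi)
        den += (n_g - 1) * m**2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    alpha = np.maximum(alpha, ALPHA_FLOOR)

    if method == "common":
        common = float(stats.trim_mean(alpha, 0.2))
        common = max(common, ALPHA_FLOOR)
        alpha = np.full_like(alpha, common)
    elif method != "per-peak":
        raise ValueError(f"unknown dispersion method {method!r}")

    return [
        DispersionEstimate(pid, float(a), method)
        for pid, a in zip(matrix.peak_ids, alpha)
    ]


def _irls_fit(
    y: np.ndarray, s: np.ndarray, x: np.ndarray, alpha: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized two-parameter NB-GLM IRLS across peaks.

    Returns (b0, b1, se_b1, converged). y: (P, n); s, x: (n,); alpha: (P,).
    """
    n_peaks = y.shape[0]
    offset = np.log(s)[None, :]

    # initial values from group means of normalized counts (pseudocount 0.5)
    q = y / s[None, :]
    ma = q[:, x == 0].mean(axis=1)
    mb = q[:, x == 1].mean(axis=1)
    b0 = np.log(np.maximum(ma, 0.5))
    b1 = np.log(np.maximum(mb, 0.5)) - b0

    alpha_col = alpha[:, None]
    converged = np.zeros(n_peaks, dtype=bool)
    active = np.ones(n_peaks, dtype=bool)
    for _ in range(IRLS_MAX_ITER):
        eta = np.clip(b0[:, None] + b1[:, None] * x[None, :], -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(offset + eta)
        w = mu / (1.0 + alpha_col * mu)
        z = eta + (y - mu) / mu

        A = w.sum(axis=1)
        B = (w * x[None, :]).sum(axis=1)
        C = (w * (x**2)[None, :]).sum(axis=1)
        r0 = (w * z).sum(axis=1)
        r1 = (w * x[None, :] * z).sum(axis=1)
        det = A * C - B**2
        det = np.where(det <= 0, np.nan, det)
        new_b0 = (C * r0 - B * r1) / det
        new_b1 = (A * r1 - B * r0) / det

        bad = ~np.isfinite(new_b0) | ~np.isfinite(new_b1)
        new_b0 = np.where(bad, b0, new_b0)
        new_b1 = np.where(bad, b1, new_b1)
        delta = np.maximum(np.abs(new_b0 - b0), np.abs(new_b1 - b1))
        b0, b1 = new_b0, new_b1
        newly = active & (delta < IRLS_TOL)
        converged |= newly
        active &= ~newly
        if not active.any():
            break

    eta = np.clip(b0[:, None] + b1[:, None] * x[None, :], -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(offset + eta)
    w = mu / (1.0 + alpha[:, None] * mu)
    A = w.sum(axis=1)
    B = (w * x[None, :]).sum(axis=1)
    C = (w * (x**2)[None, :]).sum(axis=1)
    det = A * C - B**2
    with np.errstate(divide="ignore", invalid="ignore"):
        se_b1 = np.sqrt(np.where(det > 0, A / det, np.nan))
    return b0, b1, se_b1, converged


def wald_test(
    matrix: CountMatrix,
    factors: SizeFactors,
    dispersions: Sequence[DispersionEstimate],
    design: Dict[str, str],
) -> List[DifferentialResult]:
    """NB-GLM Wald test of the group coefficient, peak by peak.

    log2FC is reported for the alphabetically second group versus the first.
    The Wald statistic z = b1/SE is referred to a t distribution with
    n_samples - 2 df. All-zero peaks get p = NaN and are excluded from the
    multiple-testing m; BH-adjusted p values are filled in over the testable
    peaks.
    """
    disp_by_peak = {d.peak_id: d.alpha for d in dispersions}
    missing = [pid for pid in matrix.peak_ids if pid not in disp_by_peak]
    if missing:
        raise ValueError(f"dispersions missing for peaks: {missing[:5]}")
    alpha = np.array([disp_by_peak[pid] for pid in matrix.peak_ids])

    s = factors.as_array(matrix.sample_ids)
    x, group_a, group_b = _group_design(matrix.sample_ids, design)
    y = matrix.counts.astype(float)

    all_zero = np.all(y == 0, axis=1)
    b0, b1, se_b1, converged = _irls_fit(y, s, x, alpha)

    base_mean = (y / s[None, :]).mean(axis=1)
    log2fc = b1 / LN2
    se_log2 = se_b1 / LN2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = b1 / se_b1
    df = max(len(matrix.sample_ids) - 2, 1)
    p = 2.0 * stats.t.sf(np.abs(z), df)
    p = np.where(all_zero | ~converged | ~np.isfinite(p), np.nan, p)
    log2fc = np.where(all_zero, 0.0, log2fc)

    results = [
        DifferentialResult(
            peak_id=pid,
            baseMean=float(base_mean[i]),
            log2FC=float(log2fc[i]),
            se=float(se_log2[i]) if np.isfinite(se_log2[i]) else float("nan"),
            p=float(p[i]),
            direction=group_b if log2fc[i] > 0 else group_a,
            converged=bool(converged[i]),
        )
        for i, pid in enumerate(matrix.peak_ids)
    ]
    padj = adjust_bh([r.p for r in results])
    for r, a in zip(results, padj):
        r.padj = a
    return results


def adjust_bh(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up over the non-NaN p values; NaN passthrough."""
    p = np.asarray(pvalues, dtype=float)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p values must lie in [0, 1]")
    out = np.full_like(p, np.nan)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def call_significant(
    results: Sequence[DifferentialResult],
    lfc_threshold: float = 1.0,
    padj_threshold: float = 0.1,
) -> Dict[str, List[DifferentialResult]]:
    """Partition by the strict thresholds |log2FC| > 1 and padj < 0.1.

    Returns {group_label: [results higher in that group], "ns": rest};
    boundary values (log2FC exactly 1, padj exactly 0.1) are not significant.
    """
    out: Dict[str, List[DifferentialResult]] = {"ns": []}
    for r in results:
        sig = (
            not math.isnan(r.padj)
            and abs(r.log2FC) > lfc_threshold
            and r.padj < padj_threshold
        )
        r.significant = sig
        if sig:
            out.setdefault(r.direction, []).append(r)
        else:
            out["ns"].append(r)
    return out
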