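"""SNP panel design: target-region and background site selection plus QC.

Target sites are common SNPs (strict MAF filter) within a fixed window on
either side of the locus, excluding the locus interval itself — the repeat
array is unmappable with short reads, so inference leans on flanking SNPs.
Background sites on other autosomes serve fetal-fraction and error-rate
estimation only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from fshd_nipd.core import (
    ConfigurationError,
    Locus,
    SNPPanel,
    SNPSite,
    chrom_sort_key,
)

logger = logging.getLogger(__name__)

#: strict minimum mean depth per sample kind
DEPTH_THRESHOLDS = {"gDNA": 40.0, "cfDNA": 300.0}


def select_target_snps(
    candidates: list[SNPSite],
    locus: Locus,
    window_bp: int = 5_000_000,
    maf_min: float = 0.30,
) -> list[SNPSite]:
    """Filter candidates to the target panel around the locus.

    Keeps sites on the locus chromosome with MAF strictly above ``maf_min``,
    within ``window_bp`` (inclusive) of the nearer locus boundary, and outside
    the locus interval. Returns the survivors sorted by position.
    """
    if not 0.0 <= maf_min <= 0.5:
        raise ConfigurationError(f"maf_min must be in [0, 0.5], got {maf_min}")
    kept = [
        s
        for s in candidates
        if s.chrom == locus.chrom
        and s.maf > maf_min
        and not locus.contains(s.pos)
        and locus.distance(s.pos) <= window_bp
    ]
    kept.sort(key=lambda s: s.pos)
    if not kept:
        logger.warning(
            "no candidate SNPs pass the target filter (maf>%.2f, +/-%d bp of %s:%d-%d)",
            maf_min, window_bp, locus.chrom, locus.start, locus.end,
        )
    return kept


def select_background_snps(
    candidates: list[SNPSite],
    n: int,
    excluded_chrom: str,
) -> list[SNPSite]:
    """Pick ``n`` sites spread over the autosomes, skipping ``excluded_chrom``.

    Chromosomes are filled round-robin; within a chromosome the picks are
    evenly spaced along the position-sorted candidates, so the result is
    scattered rather than clustered.
    """
    if n < 0:
        raise ConfigurationError(f"n must be >= 0, got {n}")
    if n == 0:
        return []
    by_chrom: dict[str, list[SNPSite]] = {}
    for s in candidates:
        if s.chrom != excluded_chrom:
            by_chrom.setdefault(s.chrom, []).append(s)
    available = sum(len(v) for v in by_chrom.values())
    if available < n:
        raise ConfigurationError(
            f"requested {n} background SNPs but only {available} candidates "
            f"available off {excluded_chrom} (short by {n - available})"
        )
    chroms = sorted(by_chrom, key=chrom_sort_key)
    # round-robin allocation of per-chromosome quotas
    quota = {c: 0 for c in chroms}
    remaining = n
    while remaining > 0:
        progressed = False
        for c in chroms:
            if remaining == 0:
                break
            if quota[c] < len(by_chrom[c]):
                quota[c] += 1
                remaining -= 1
                progressed = True
        if not progressed:  # pragma: no cover - guarded by the shortfall check
            raise ConfigurationError("background allocation failed")
    selected: list[SNPSite] = []
    for c in chroms:
        k = quota[c]
        if k == 0:
            continue
        pool = sorted(by_chrom[c], key=lambda s: s.pos)
        idx = np.unique(np.round(np.linspace(0, len(pool) - 1, k)).astype(int))
        # rounding collisions: top up with the remaining nearest indices
        if len(idx) < k:
            extra = [i for i in range(len(pool)) if i not in set(idx)][: k - len(idx)]
            idx = np.sort(np.concatenate([idx, np.array(extra, dtype=int)]))
        selected.extend(pool[i] for i in idx)
    return selected


def panel_stats(panel: SNPPanel) -> dict:
    """Site counts and inter-site spacing summary on the target region."""
    positions = panel.target_positions
    stats: dict[str, object] = {
        "n_target": len(panel.target_sites),
        "n_background": len(panel.background_sites),
        "window_bp": panel.window_bp,
    }
    if len(positions) >= 2:
        gaps = np.diff(positions)
        stats.update(
            median_spacing_bp=float(np.median(gaps)),
            min_spacing_bp=int(gaps.min()),
            max_spacing_bp=int(gaps.max()),
        )
    else:
        stats.update(median_spacing_bp=None, min_spacing_bp=None, max_spacing_bp=None)
    return stats


@dataclass
class DepthQC:
    passed: bool
    mean_depth: float | None
    threshold: float
    sample_kind: str
    reason: str | None = None


def qc_depth(depths, sample_kind: str) -> DepthQC:
    """Check mean on-target depth against the per-kind threshold (strict >).

    ``depths`` is any array-like of per-site read depths. gDNA samples must
    exceed 40X on average, cfDNA 300X.
    """
    if sample_kind not in DEPTH_THRESHOLDS:
        raise ConfigurationError(f"sample_kind must be one of {set(DEPTH_THRESHOLDS)}")
    threshold = DEPTH_THRESHOLDS[sample_kind]
    arr = np.asarray(depths, dtype=float)
    if arr.size == 0:
        return DepthQC(False, None, threshold, sample_kind, reason="no coverage")
    mean = float(arr.mean())
    passed = mean > threshold
    return DepthQC(passed, mean, threshold, sample_kind,
                   reason=None if passed else f"mean depth {mean:.1f} <= {threshold:.0f}")
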