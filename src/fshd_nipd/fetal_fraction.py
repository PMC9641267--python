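"""Fetal-fraction and sequencing-error estimation from background SNPs.

At sites where the two parents are homozygous for *different* alleles the
fetus is an obligate heterozygote, so plasma reads of the paternal-specific
allele all come from fetal DNA and appear at frequency f/2. Pooling counts
over such sites gives

    f = 2 Σp / Σ(p + q)

with p the paternal-specific-allele reads and q the maternal-allele reads.
At sites where both parents are homozygous for the *same* allele the fetus
is an obligate homozygote, so any read of the other allele is a sequencing
error; pooling those gives the per-read error rate ε.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from fshd_nipd.core import (
    ErrorRateEstimate,
    EstimationError,
    FetalFractionEstimate,
    GenotypeTable,
)

logger = logging.getLogger(__name__)


def select_ff_sites(genotypes: GenotypeTable) -> pd.DataFrame:
    """Sites where father and mother are homozygous for different alleles.

    Returns a frame with ``chrom, pos, ref, alt, paternal_is_alt`` (which
    allele is paternal-specific). Sites with a missing parental genotype are
    skipped; the skip count is attached as ``.attrs['n_skipped_missing']``.
    """
    fa = genotypes.dosages("father")
    mo = genotypes.dosages("mother")
    missing = (fa == -1) | (mo == -1)
    informative = ~missing & np.isin(fa, (0, 2)) & np.isin(mo, (0, 2)) & (fa != mo)
    out = genotypes.df.loc[informative, ["chrom", "pos", "ref", "alt"]].reset_index(drop=True)
    out["paternal_is_alt"] = (fa[informative] == 2)
    out.attrs["n_skipped_missing"] = int(missing.sum())
    if missing.any():
        logger.info("select_ff_sites: skipped %d sites with missing parental genotypes", int(missing.sum()))
    return out


def _merge_counts(counts: pd.DataFrame, sites: pd.DataFrame, sample_id: str | None):
    sub = counts
    if sample_id is not None:
        sub = counts[counts["sample_id"] == sample_id]
    return sub.merge(sites, on=["chrom", "pos"], how="inner", suffixes=("", "_panel"))


def estimate_fetal_fraction(
    counts: pd.DataFrame,
    ff_sites: pd.DataFrame,
    sample_id: str | None = None,
) -> FetalFractionEstimate:
    """Estimate f = 2Σp / Σ(p+q) over the paternal-specific sites.

    ``counts`` is a plasma count table (chrom, pos, ref_count, alt_count,
    sample_id); ``ff_sites`` comes from :func:`select_ff_sites`. Reads of
    neither parental allele are not represented in the two-count format and
    are therefore excluded by construction. An estimate above 1 is capped
    and flagged (possible sample swap).
    """
    merged = _merge_counts(counts, ff_sites, sample_id)
    if len(merged) == 0:
        raise EstimationError("no fetal-fraction sites present in the plasma counts")
    p = np.where(merged["paternal_is_alt"], merged["alt_count"], merged["ref_count"])
    q = np.where(merged["paternal_is_alt"], merged["ref_count"], merged["alt_count"])
    sum_p, sum_q = int(p.sum()), int(q.sum())
    if sum_p + sum_q == 0:
        raise EstimationError("zero total depth at fetal-fraction sites")
    f = 2.0 * sum_p / (sum_p + sum_q)
    capped = f > 1.0
    if capped:
        logger.warning("fetal fraction estimate %.3f > 1 capped to 1.0 (possible sample swap)", f)
        f = 1.0
    n_used = int(((p + q) > 0).sum())
    sid = sample_id
    if sid is None and counts["sample_id"].nunique() == 1:
        sid = str(counts["sample_id"].iloc[0])
    return FetalFractionEstimate(f=f, sum_p=sum_p, sum_q=sum_q, n_sites_used=n_used,
                                 sample_id=sid, capped=capped)


def estimate_error_rate(
    counts: pd.DataFrame,
    genotypes: GenotypeTable,
    sample_id: str | None = None,
) -> ErrorRateEstimate:
    """Pooled per-read error rate at double-homozygous-concordant sites.

    Where both parents are homozygous for the same allele the fetus must be
    homozygous for it too, so every read of the absent allele is an error:
    ε = (absent-allele reads) / (total reads), pooled over sites.
    """
    fa = genotypes.dosages("father")
    mo = genotypes.dosages("mother")
    eligible = np.isin(fa, (0, 2)) & (fa == mo)
    sites = genotypes.df.loc[eligible, ["chrom", "pos"]].copy()
    sites["expected_is_alt"] = (fa[eligible] == 2)
    if len(sites) == 0:
        raise EstimationError("no sites with both parents homozygous for the same allele")
    merged = _merge_counts(counts, sites, sample_id)
    if len(merged) == 0:
        raise EstimationError("no error-rate sites present in the plasma counts")
    mism = np.where(merged["expected_is_alt"], merged["ref_count"], merged["alt_count"])
    total = (merged["ref_count"] + merged["alt_count"]).to_numpy()
    if total.sum() == 0:
        raise EstimationError("zero total depth at error-rate sites")
    return ErrorRateEstimate(
        epsilon=float(mism.sum() / total.sum()),
        n_sites_used=int((total > 0).sum()),
        mismatched_reads=int(mism.sum()),
        total_reads=int(total.sum()),
    )


def estimate_per_sample(
    counts: pd.DataFrame,
    genotypes: GenotypeTable,
) -> tuple[list[FetalFractionEstimate], ErrorRateEstimate]:
    """One fetal-fraction estimate per plasma sample plus a pooled error rate."""
    ff_sites = select_ff_sites(genotypes)
    estimates = [
        estimate_fetal_fraction(counts, ff_sites, sample_id=sid)
        for sid in sorted(counts["sample_id"].unique())
    ]
    eps = estimate_error_rate(counts, genotypes)
    return estimates, eps


def summarize_fetal_fraction(estimates: list[FetalFractionEstimate]) -> dict:
    """min/median/max of f across plasma samples."""
    if not estimates:
        raise EstimationError("no fetal-fraction estimates to summarize")
    fs = np.array([e.f for e in estimates])
    return {
        "min": float(fs.min()),
        "median": float(np.median(fs)),
        "max": float(fs.max()),
        "n_samples": len(estimates),
    }
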