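"""Informative-SNP selection and trio phasing of the paternal haplotypes.

A site is informative when the father is heterozygous, exactly one paternal
grandparent is heterozygous with the other homozygous, and the mother is
homozygous. The homozygous grandparent pins which paternal allele came from
which grandparent, so the father's phase is forced; maternal homozygosity is
what later makes the paternal alleles distinguishable in plasma. The
haplotype transmitted by the affected grandparent is labelled hap0 (the
pathogenic haplotype), the other hap1.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fshd_nipd.core import (
    GenotypeTable,
    PaternalHaplotypes,
    PhasingError,
    SNPPanel,
    dosage_to_gt,
    parse_gt,
)

logger = logging.getLogger(__name__)

_ALLELES = {0: (0, 0), 1: (0, 1), 2: (1, 1)}


def _father_consistent(gf: int, gm: int, father: int) -> bool:
    """Can the father's genotype be formed from one allele of each grandparent?"""
    target = _ALLELES[father]
    return any(
        tuple(sorted((a, b))) == target
        for a in _ALLELES[gf]
        for b in _ALLELES[gm]
    )


def enumerate_informative_configs() -> list[tuple[str, str, str, str]]:
    """Brute-force the informative genotype configurations.

    Enumerates all assignments of {0/0, 0/1, 1/1} to (grandfather,
    grandmother, father, mother) and keeps those with the father
    heterozygous, exactly one grandparent heterozygous and the other
    homozygous, the mother homozygous, and the father Mendelian-consistent
    with the grandparents. Returned in a canonical order: grandfather-
    heterozygous block first, then by the homozygous grandparent's genotype,
    then by the mother's.
    """
    configs = []
    for gf, gm, fa, mo in itertools.product((0, 1, 2), repeat=4):
        if fa != 1:
            continue
        if (gf == 1) == (gm == 1):  # exactly one grandparent heterozygous
            continue
        if mo == 1:
            continue
        if not _father_consistent(gf, gm, fa):
            continue
        configs.append((gf, gm, fa, mo))
    configs.sort(key=lambda t: (0 if t[0] == 1 else 1, t[1] if t[0] == 1 else t[0], t[3]))
    return [tuple(dosage_to_gt(d) for d in cfg) for cfg in configs]


_INFORMATIVE_DOSAGES: frozenset[tuple[int, int, int, int]] = frozenset(
    tuple(parse_gt(g) for g in cfg) for cfg in enumerate_informative_configs()
)


def is_informative(gf_gt, gm_gt, father_gt, mother_gt) -> bool:
    """True iff the genotype 4-tuple allows phased paternal-dosage inference.

    Accepts genotype strings or dosages; any missing genotype is
    non-informative.
    """
    try:
        tup = tuple(parse_gt(g) for g in (gf_gt, gm_gt, father_gt, mother_gt))
    except ValueError:
        return False
    if -1 in tup:
        return False
    return tup in _INFORMATIVE_DOSAGES


@dataclass
class InformativeSelection:
    """Informative target-region sites plus selection diagnostics."""

    table: GenotypeTable
    n_informative: int
    nearest_distance_bp: int
    nearest_pos: int
    n_skipped_missing: int


def select_informative_snps(genotypes: GenotypeTable, panel: SNPPanel) -> InformativeSelection:
    """Select informative SNPs on the target region, position-sorted.

    Raises :class:`PhasingError` when no site is informative, since haplotype
    inference is then impossible.
    """
    target = genotypes.restrict_to(panel.target_sites)
    gf = target.dosages("grandfather")
    gm = target.dosages("grandmother")
    fa = target.dosages("father")
    mo = target.dosages("mother")
    missing = (gf == -1) | (gm == -1) | (fa == -1) | (mo == -1)
    mask = np.array(
        [
            not m and (int(a), int(b), int(c), int(d)) in _INFORMATIVE_DOSAGES
            for m, a, b, c, d in zip(missing, gf, gm, fa, mo)
        ],
        dtype=bool,
    )
    n_missing = int(missing.sum())
    if n_missing:
        logger.info("skipped %d target sites with missing genotypes", n_missing)
    if not mask.any():
        raise PhasingError("no informative SNPs on the target region; cannot phase")
    selected = target.subset(mask)
    dists = np.array([panel.locus.distance(int(p)) for p in selected.positions])
    i_near = int(np.argmin(dists))
    return InformativeSelection(
        table=selected,
        n_informative=len(selected),
        nearest_distance_bp=int(dists[i_near]),
        nearest_pos=int(selected.positions[i_near]),
        n_skipped_missing=n_missing,
    )


@dataclass
class PhasingResult:
    haplotypes: PaternalHaplotypes
    rejected_sites: pd.DataFrame = field(default_factory=pd.DataFrame)


def phase_paternal(
    genotypes: GenotypeTable,
    affected_source: str = "grandmother",
) -> PhasingResult:
    """Phase the father's alleles into hap0/hap1 at informative sites.

    At each site the homozygous grandparent's allele is the one the father
    inherited from that grandparent; the complementary allele (the father is
    heterozygous) came from the heterozygous grandparent. hap0 collects the
    alleles transmitted by ``affected_source``. Sites failing the
    informativeness/Mendelian conditions are rejected and returned, not
    fatal.
    """
    if affected_source not in ("grandfather", "grandmother"):
        raise PhasingError(f"affected_source must be a grandparent, got {affected_source!r}")
    df = genotypes.df
    gf = genotypes.dosages("grandfather")
    gm = genotypes.dosages("grandmother")
    fa = genotypes.dosages("father")
    mo = genotypes.dosages("mother")
    ok = np.array(
        [
            (int(a), int(b), int(c), int(d)) in _INFORMATIVE_DOSAGES
            for a, b, c, d in zip(gf, gm, fa, mo)
        ],
        dtype=bool,
    )
    rejected = df.loc[~ok, ["chrom", "pos", "ref", "alt"]].reset_index(drop=True)
    if len(rejected):
        logger.warning("rejected %d non-informative/inconsistent sites during phasing", len(rejected))
    gf, gm = gf[ok], gm[ok]
    # which grandparent is homozygous at each site (exactly one, by selection)
    gf_is_hom = gf != 1
    hom_allele = np.where(gf_is_hom, gf // 2, gm // 2).astype(np.int8)
    from_gf = np.where(gf_is_hom, hom_allele, 1 - hom_allele).astype(np.int8)
    from_gm = (1 - from_gf).astype(np.int8)
    hap0 = from_gm if affected_source == "grandmother" else from_gf
    hap1 = (1 - hap0).astype(np.int8)
    haps = PaternalHaplotypes(
        sites=df.loc[ok, ["chrom", "pos", "ref", "alt"]].reset_index(drop=True),
        hap0=hap0,
        hap1=hap1,
        affected_source=affected_source,
    )
    return PhasingResult(haplotypes=haps, rejected_sites=rejected)


def mendelian_check(genotypes: GenotypeTable) -> pd.DataFrame:
    """Flag sites where the father's genotype is impossible given the grandparents.

    Sites with any missing genotype among the trio are skipped. Returns the
    violating rows (chrom, pos plus the three genotypes).
    """
    gf = genotypes.dosages("grandfather")
    gm = genotypes.dosages("grandmother")
    fa = genotypes.dosages("father")
    rows = []
    for i, (a, b, c) in enumerate(zip(gf, gm, fa)):
        if -1 in (a, b, c):
            continue
        if not _father_consistent(int(a), int(b), int(c)):
            rows.append(i)
    cols = ["chrom", "pos", "grandfather", "grandmother", "father"]
    return genotypes.df.loc[rows, cols].reset_index(drop=True)
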