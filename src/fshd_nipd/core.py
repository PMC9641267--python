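"""Shared domain containers: loci, SNP sites, panels, genotype tables.

Conventions used throughout the package:

* coordinates are 1-based inclusive (VCF convention); BED output converts
  to 0-based half-open at the I/O boundary;
* diploid genotypes are stored as alt-allele dosage: 0 (``0/0``),
  1 (``0/1``), 2 (``1/1``); ``-1`` marks a missing genotype;
* family roles are ``grandfather``, ``grandmother``, ``father``, ``mother``
  (the paternal grandparents resolve the father's phase; the fetus is never
  genotyped directly).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ROLES = ("grandfather", "grandmother", "father", "mother")

#: canonical column order for plasma allele-count tables
PLASMA_COLUMNS = ("chrom", "pos", "ref", "alt", "ref_count", "alt_count", "sample_id")

_GT_TO_DOSAGE = {
    "0/0": 0, "0|0": 0,
    "0/1": 1, "1/0": 1, "0|1": 1, "1|0": 1,
    "1/1": 2, "1|1": 2,
    "./.": -1, ".": -1, ".|.": -1,
}
_DOSAGE_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


class NIPDError(Exception):
    """Base class for pipeline errors."""


class ConfigurationError(NIPDError):
    """Invalid configuration or insufficient candidates for a request."""


class EstimationError(NIPDError):
    """Fetal-fraction or error-rate estimation impossible on the given data."""


class PhasingError(NIPDError):
    """Paternal haplotype cannot be phased (e.g. zero informative sites)."""


class InferenceError(NIPDError):
    """HMM inference cannot run (e.g. empty observation sequence)."""


class ConsistencyError(NIPDError):
    """Internal labeling contradiction, e.g. a 'pathogenic' haplotype whose
    attached D4Z4 allele classifies as normal."""


def parse_gt(gt: str | int | None) -> int:
    """Parse a VCF-style genotype string into an alt-allele dosage."""
    if gt is None:
        return -1
    if isinstance(gt, (int, np.integer)):
        d = int(gt)
        if d not in (-1, 0, 1, 2):
            raise ValueError(f"invalid dosage {gt!r}")
        return d
    try:
        return _GT_TO_DOSAGE[gt.strip()]
    except KeyError:
        raise ValueError(f"unrecognised genotype {gt!r}") from None


def dosage_to_gt(d: int) -> str:
    return _DOSAGE_TO_GT[int(d)]


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Natural ordering for chromosome labels (chr1 < chr2 < ... < chrX)."""
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return (int(c), "") if c.isdigit() else (10**9, c)


@dataclass(frozen=True)
class Locus:
    """A 1-based inclusive genomic interval (the D4Z4 proxy interval)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ConfigurationError(f"invalid locus {self.chrom}:{self.start}-{self.end}")

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def distance(self, pos: int) -> int:
        """Distance in bp from ``pos`` to the nearest locus boundary (0 inside)."""
        if self.contains(pos):
            return 0
        return min(abs(pos - self.start), abs(pos - self.end))

    @classmethod
    def parse(cls, text: str) -> "Locus":
        """Parse ``chrom:start-end`` (1-based inclusive)."""
        chrom, _, span = text.partition(":")
        start, _, end = span.partition("-")
        return cls(chrom, int(start.replace(",", "")), int(end.replace(",", "")))


@dataclass(frozen=True)
class SNPSite:
    """A biallelic SNP with its population alternate-allele frequency."""

    chrom: str
    pos: int
    ref: str
    alt: str
    alt_freq: float

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not 0.0 <= self.alt_freq <= 1.0:
            raise ValueError(f"alt_freq out of [0,1] at {self.chrom}:{self.pos}")

    @property
    def maf(self) -> float:
        return min(self.alt_freq, 1.0 - self.alt_freq)


def sites_to_frame(sites: Iterable[SNPSite]) -> pd.DataFrame:
    rows = [(s.chrom, s.pos, s.ref, s.alt, s.alt_freq) for s in sites]
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "alt_freq"])


def frame_to_sites(df: pd.DataFrame) -> list[SNPSite]:
    return [
        SNPSite(str(r.chrom), int(r.pos), str(r.ref), str(r.alt), float(r.alt_freq))
        for r in df.itertuples(index=False)
    ]


@dataclass
class SNPPanel:
    """Target sites flanking the locus plus background sites on other autosomes."""

    locus: Locus
    target_sites: list[SNPSite]
    background_sites: list[SNPSite]
    window_bp: int

    def __post_init__(self) -> None:
        seen: set[tuple[str, int]] = set()
        for s in list(self.target_sites) + list(self.background_sites):
            key = (s.chrom, s.pos)
            if key in seen:
                raise ValueError(f"duplicate panel site {s.chrom}:{s.pos}")
            seen.add(key)
        for s in self.target_sites:
            if s.chrom != self.locus.chrom:
                raise ValueError("target site off the locus chromosome")
            if self.locus.contains(s.pos):
                raise ValueError(f"target site inside the locus at {s.pos}")
            if self.locus.distance(s.pos) > self.window_bp:
                raise ValueError(f"target site beyond the window at {s.pos}")
        for s in self.background_sites:
            if s.chrom == self.locus.chrom:
                raise ValueError("background site on the locus chromosome")

    @property
    def target_positions(self) -> np.ndarray:
        return np.array(sorted(s.pos for s in self.target_sites), dtype=np.int64)


class GenotypeTable:
    """Role-keyed diploid genotypes over a set of sites.

    Backed by a DataFrame with columns ``chrom, pos, ref, alt`` plus one
    int8 dosage column per role (``-1`` = missing), sorted by (chrom, pos).
    """

    SITE_COLUMNS = ("chrom", "pos", "ref", "alt")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in (*self.SITE_COLUMNS, *ROLES) if c not in df.columns]
        if missing:
            raise ValueError(f"genotype table missing columns: {missing}")
        df = df.copy()
        for role in ROLES:
            col = df[role]
            if col.dtype == object:
                col = col.map(parse_gt)
            df[role] = col.astype(np.int8)
            if not df[role].isin([-1, 0, 1, 2]).all():
                raise ValueError(f"invalid dosage values in column {role!r}")
        df["_ck"] = df["chrom"].map(chrom_sort_key)
        df = df.sort_values(["_ck", "pos"], kind="stable").drop(columns="_ck")
        df = df.reset_index(drop=True)
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def dosages(self, role: str) -> np.ndarray:
        if role not in ROLES:
            raise KeyError(f"unknown role {role!r}")
        return self.df[role].to_numpy()

    @property
    def positions(self) -> np.ndarray:
        return self.df["pos"].to_numpy()

    @property
    def chroms(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()

    def subset(self, mask: np.ndarray) -> "GenotypeTable":
        return GenotypeTable(self.df.loc[np.asarray(mask)].reset_index(drop=True))

    def restrict_to(self, sites: Sequence[SNPSite]) -> "GenotypeTable":
        keys = {(s.chrom, s.pos) for s in sites}
        mask = [
            (c, p) in keys
            for c, p in zip(self.df["chrom"], self.df["pos"])
        ]
        return self.subset(np.array(mask, dtype=bool))

    @classmethod
    def from_arrays(
        cls,
        sites: pd.DataFrame | Sequence[SNPSite],
        **dosages: np.ndarray,
    ) -> "GenotypeTable":
        """Build from a site frame/list plus one dosage array per role."""
        df = sites.copy() if isinstance(sites, pd.DataFrame) else sites_to_frame(sites)
        df = df[[c for c in df.columns if c in (*cls.SITE_COLUMNS, "alt_freq")]]
        for role in ROLES:
            if role not in dosages:
                raise ValueError(f"missing dosage array for role {role!r}")
            df[role] = np.asarray(dosages[role], dtype=np.int8)
        return cls(df)


@dataclass
class PaternalHaplotypes:
    """The father's two phased haplotypes over the informative sites.

    ``hap0`` is the haplotype transmitted by the affected grandparent (the
    pathogenic haplotype); ``hap1`` is the normal one. Alleles are coded
    0 = ref, 1 = alt; the father is heterozygous at every informative site,
    so ``hap0 != hap1`` everywhere.
    """

    sites: pd.DataFrame  # chrom, pos, ref, alt
    hap0: np.ndarray
    hap1: np.ndarray
    affected_source: str

    def __post_init__(self) -> None:
        self.hap0 = np.asarray(self.hap0, dtype=np.int8)
        self.hap1 = np.asarray(self.hap1, dtype=np.int8)
        if len(self.hap0) != len(self.sites) or len(self.hap1) != len(self.sites):
            raise ValueError("haplotype arrays must match the site table")
        if np.any(self.hap0 == self.hap1):
            raise ValueError("hap0 == hap1 at some site: father not heterozygous")
        if self.affected_source not in ("grandfather", "grandmother"):
            raise ValueError(f"affected_source must be a grandparent, got {self.affected_source!r}")

    def __len__(self) -> int:
        return len(self.hap0)


@dataclass
class FetalFractionEstimate:
    """Fetal fraction from paternal-specific allele counts: f = 2Σp / Σ(p+q)."""

    f: float
    sum_p: int
    sum_q: int
    n_sites_used: int
    sample_id: str | None = None
    capped: bool = False


@dataclass
class ErrorRateEstimate:
    """Pooled per-read sequencing error rate from obligate-homozygous sites."""

    epsilon: float
    n_sites_used: int
    mismatched_reads: int
    total_reads: int


@dataclass(frozen=True)
class D4Z4Allele:
    """One D4Z4 macrosatellite allele: repeat-unit count and distal haplotype.

    Only a contracted array (1-10 units) on a 4qA distal background is
    disease-permissive for FSHD1.
    """

    repeat_count: int
    distal_type: str  # "4qA" or "4qB"

    def __post_init__(self) -> None:
        if self.repeat_count < 1:
            raise ValueError(f"repeat_count must be >= 1, got {self.repeat_count}")
        if self.distal_type not in ("4qA", "4qB"):
            raise ValueError(f"distal_type must be 4qA or 4qB, got {self.distal_type!r}")
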