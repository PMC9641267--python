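"""Synthetic three-generation families with plasma read counts.

The generator emulates the study design end-to-end: a target SNP panel in a
fixed window around the D4Z4 proxy locus plus background autosomal SNPs,
Hardy-Weinberg founder haplotypes, Mendelian transmission with Haldane-model
recombination (grandparents -> father, mother -> fetus, father -> fetus), a
pathogenic D4Z4 allele (contracted array, 4qA) attached to the affected
grandparent's transmitted haplotype, and maternal plasma allele counts as a
(1-f)/f maternal/fetal mixture with symmetric per-read error at Poisson
depth. Every stochastic choice is driven by one seed, and the full ground
truth (phases, transmitted haplotypes, breakpoints, D4Z4 alleles) is
returned for downstream verification.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from fshd_nipd.core import (
    PLASMA_COLUMNS,
    ConfigurationError,
    D4Z4Allele,
    GenotypeTable,
    Locus,
    SNPSite,
    chrom_sort_key,
    sites_to_frame,
)

_BASES = np.array(list("ACGT"))
_AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))
#: nominal autosome length used to scatter background sites (positions are
#: treated as opaque; no build is implied)
_BG_CHROM_SPAN = 130_000_000


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic family generator.

    Defaults mirror the targeted-capture design: 567 target SNPs with
    MAF > 0.30 in a 5 Mb window each side of the locus, 1,262 background
    autosomal SNPs, ~300X cfDNA and ~40X gDNA mean depths, per-read error
    6e-4, fetal fraction at the reported median 15.58%, and a uniform
    1 cM/Mb recombination rate.
    """

    locus: Locus = field(default_factory=lambda: Locus("chr4", 190_060_000, 190_100_000))
    window_bp: int = 5_000_000
    n_target_snps: int = 567
    n_background_snps: int = 1262
    maf_min: float = 0.30
    fetal_fraction: float = 0.1558
    error_rate: float = 6e-4
    mean_depth_cfdna: float = 300.0
    mean_depth_gdna: float = 40.0
    recomb_rate_c: float = 1e-8  # Morgans per bp
    forced_breakpoints: tuple[int, ...] = ()
    affected_grandparent: str = "grandmother"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.forced_breakpoints = tuple(int(b) for b in self.forced_breakpoints)
        self.validate()

    def validate(self) -> None:
        if not 0.0 < self.fetal_fraction < 1.0:
            raise ConfigurationError(f"fetal_fraction must be in (0,1), got {self.fetal_fraction}")
        if not 0.0 <= self.error_rate <= 0.01:
            raise ConfigurationError(f"error_rate must be in [0, 0.01], got {self.error_rate}")
        if not 0.0 <= self.maf_min <= 0.5:
            raise ConfigurationError(f"maf_min must be in [0, 0.5], got {self.maf_min}")
        if self.mean_depth_cfdna <= 0 or self.mean_depth_gdna <= 0:
            raise ConfigurationError("mean depths must be positive")
        if self.recomb_rate_c < 0:
            raise ConfigurationError("recomb_rate_c must be >= 0")
        if self.n_target_snps < 1 or self.n_background_snps < 0 or self.window_bp < 1:
            raise ConfigurationError("panel sizes and window must be positive")
        if self.affected_grandparent not in ("grandfather", "grandmother"):
            raise ConfigurationError(
                f"affected_grandparent must be a grandparent, got {self.affected_grandparent!r}"
            )
        lo = self.locus.start - self.window_bp
        hi = self.locus.end + self.window_bp
        for b in self.forced_breakpoints:
            if not lo <= b <= hi:
                raise ConfigurationError(f"forced breakpoint {b} outside the panel window [{lo},{hi}]")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "locus" in d and not isinstance(d["locus"], Locus):
            loc = d["locus"]
            d["locus"] = Locus.parse(loc) if isinstance(loc, str) else Locus(**loc)
        if "forced_breakpoints" in d and d["forced_breakpoints"] is not None:
            d["forced_breakpoints"] = tuple(d["forced_breakpoints"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["locus"] = {"chrom": self.locus.chrom, "start": self.locus.start, "end": self.locus.end}
        d["forced_breakpoints"] = list(self.forced_breakpoints)
        return d


@dataclass
class SimTruth:
    """Ground truth for one simulated family.

    Arrays are aligned with the (chrom, pos)-sorted site table. The fetal
    paternal-inheritance state is 0 where the fetus carries hap0 (the
    affected grandparent's transmitted haplotype) and 1 where it carries
    hap1; it changes only at the realized breakpoints.
    """

    sites: pd.DataFrame
    haplotypes: dict  # role -> (n, 2) int8 array of phased alleles
    father_hap0: np.ndarray
    father_hap1: np.ndarray
    fetal_paternal_state: np.ndarray  # 0 = hap0, 1 = hap1
    fetal_paternal_allele: np.ndarray
    fetal_maternal_allele: np.ndarray
    breakpoints: list  # (chrom, pos) from the fetal paternal meiosis
    d4z4: dict  # father_hap0 / father_hap1 / fetal_paternal / fetal_maternal -> D4Z4Allele
    affected_grandparent: str
    locus: Locus
    _locus_start_state: int = 0  # fetal paternal state left of the first locus-chrom breakpoint

    @property
    def fetal_dosage(self) -> np.ndarray:
        return (self.fetal_paternal_allele + self.fetal_maternal_allele).astype(np.int8)

    def locus_chrom_breakpoints(self) -> list[int]:
        return sorted(p for c, p in self.breakpoints if c == self.locus.chrom)

    def paternal_state_at(self, pos: int) -> int:
        """Fetal paternal-inheritance state (0=hap0, 1=hap1) at a locus-chromosome position."""
        n_flips = sum(1 for b in self.locus_chrom_breakpoints() if b <= pos)
        return (self._locus_start_state + n_flips) % 2

    def to_dict(self) -> dict:
        return {
            "affected_grandparent": self.affected_grandparent,
            "breakpoints": [[c, int(p)] for c, p in self.breakpoints],
            "d4z4": {
                k: {"repeat_count": a.repeat_count, "distal_type": a.distal_type}
                for k, a in self.d4z4.items()
            },
            "fetal_paternal_state": self.fetal_paternal_state.astype(int).tolist(),
            "sites": self.sites[["chrom", "pos"]].to_dict(orient="list"),
        }


def _rng_for(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, config.rng_seed])


def _sample_distinct(rng: np.random.Generator, n_available: int, n: int) -> np.ndarray:
    """n distinct integers from [0, n_available), sorted."""
    if n > n_available:
        raise ConfigurationError(
            f"cannot place {n} distinct sites in {n_available} available positions"
        )
    pool = np.array([], dtype=np.int64)
    while len(pool) < n:
        extra = rng.integers(0, n_available, size=2 * n + 16)
        pool = np.unique(np.concatenate([pool, extra]))
    return np.sort(rng.choice(pool, size=n, replace=False))


def _draw_site_fields(rng: np.random.Generator, n: int, maf_min: float):
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    maf = rng.uniform(maf_min, 0.5, size=n)
    minor_is_alt = rng.random(n) < 0.5
    alt_freq = np.where(minor_is_alt, maf, 1.0 - maf)
    return _BASES[ref_idx], _BASES[alt_idx], alt_freq


def simulate_population_sites(config: SimConfig, rng: np.random.Generator | None = None) -> list[SNPSite]:
    """Draw the target + background SNP sites the panel will genotype.

    Target sites are uniform over the window on either flank of the locus
    (never inside it) with MAF uniform on [maf_min, 0.5]; background sites
    are scattered round-robin over the other autosomes.
    """
    config.validate()
    rng = rng or _rng_for(config, 0)
    loc, w = config.locus, config.window_bp
    # target: index space [0, 2w) maps to the left then right flank
    idx = _sample_distinct(rng, 2 * w, config.n_target_snps)
    pos = np.where(idx < w, loc.start - w + idx, loc.end + 1 + (idx - w))
    ref, alt, alt_freq = _draw_site_fields(rng, len(pos), config.maf_min)
    sites = [
        SNPSite(loc.chrom, int(p), str(r), str(a), float(q))
        for p, r, a, q in zip(pos, ref, alt, alt_freq)
    ]
    # background: round-robin across the other autosomes
    bg_chroms = [c for c in _AUTOSOMES if c != loc.chrom]
    quota = {c: 0 for c in bg_chroms}
    for i in range(config.n_background_snps):
        quota[bg_chroms[i % len(bg_chroms)]] += 1
    for c in bg_chroms:
        k = quota[c]
        if k == 0:
            continue
        bpos = _sample_distinct(rng, _BG_CHROM_SPAN, k) + 1
        ref, alt, alt_freq = _draw_site_fields(rng, k, config.maf_min)
        sites.extend(
            SNPSite(c, int(p), str(r), str(a), float(q))
            for p, r, a, q in zip(bpos, ref, alt, alt_freq)
        )
    return sites


def _chrom_groups(chroms: np.ndarray):
    """Yield (chrom, slice) over contiguous chromosome blocks of a sorted table."""
    start = 0
    for i in range(1, len(chroms) + 1):
        if i == len(chroms) or chroms[i] != chroms[start]:
            yield chroms[start], slice(start, i)
            start = i


def _meiosis(
    hap_a: np.ndarray,
    hap_b: np.ndarray,
    chroms: np.ndarray,
    positions: np.ndarray,
    c: float,
    rng: np.random.Generator,
    forced: Sequence[int] | None = None,
    forced_chrom: str | None = None,
):
    """One gamete from a diploid parent under the Haldane map.

    Returns (source, gamete, breakpoints): ``source[i]`` is 0/1 for which
    parental haplotype site i descends from, ``gamete`` the resulting allele
    vector, and ``breakpoints`` the realized crossover positions as
    (chrom, pos) with the convention that the new segment starts AT the
    breakpoint coordinate (sites with pos >= breakpoint lie downstream of
    the switch).
    """
    n = len(positions)
    source = np.zeros(n, dtype=np.int8)
    breakpoints: list[tuple[str, int]] = []
    start_states: dict[str, int] = {}
    forced = sorted(forced) if forced else []
    for chrom, sl in _chrom_groups(chroms):
        pos = positions[sl]
        s0 = int(rng.integers(0, 2))
        start_states[chrom] = s0
        if forced and chrom == forced_chrom:
            flips = np.searchsorted(np.asarray(forced), pos, side="right")
            source[sl] = (s0 + flips) % 2
            breakpoints.extend((chrom, int(b)) for b in forced)
            continue
        if len(pos) > 1 and c > 0:
            d = np.diff(pos).astype(float)
            r = 0.5 * (1.0 - np.exp(-2.0 * c * d))
            switch = rng.random(len(d)) < r
            source[sl] = (s0 + np.concatenate([[0], np.cumsum(switch)])) % 2
            for i in np.flatnonzero(switch):
                bp = int(rng.integers(pos[i] + 1, pos[i + 1] + 1))
                breakpoints.append((chrom, bp))
        else:
            source[sl] = s0
    gamete = np.where(source == 0, hap_a, hap_b).astype(np.int8)
    return source, gamete, breakpoints, start_states


def simulate_family(
    sites: list[SNPSite],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeTable, SimTruth]:
    """Simulate the three-generation family over the given sites.

    Grandparental and maternal haplotypes are independent Hardy-Weinberg
    draws from each site's population frequency; the father receives one
    recombined gamete from each grandparent; the fetus receives one maternal
    gamete and one paternal gamete (recombining the father's two
    haplotypes, at ``forced_breakpoints`` when provided). hap0 denotes the
    father's haplotype inherited from the affected grandparent, and the
    pathogenic D4Z4 allele (<=10 repeat units, 4qA) rides on it.
    """
    if not sites:
        raise ConfigurationError("no sites to simulate")
    config.validate()
    rng = rng or _rng_for(config, 1)
    frame = sites_to_frame(sites)
    frame["_ck"] = frame["chrom"].map(chrom_sort_key)
    frame = frame.sort_values(["_ck", "pos"], kind="stable").drop(columns="_ck").reset_index(drop=True)
    chroms = frame["chrom"].to_numpy()
    positions = frame["pos"].to_numpy()
    p_alt = frame["alt_freq"].to_numpy()
    n = len(frame)
    c = config.recomb_rate_c

    founders = {}
    for role in ("grandfather", "grandmother", "mother"):
        founders[role] = (rng.random((n, 2)) < p_alt[:, None]).astype(np.int8)

    _, hap_from_gf, _, _ = _meiosis(
        founders["grandfather"][:, 0], founders["grandfather"][:, 1], chroms, positions, c, rng
    )
    _, hap_from_gm, _, _ = _meiosis(
        founders["grandmother"][:, 0], founders["grandmother"][:, 1], chroms, positions, c, rng
    )
    _, maternal_gamete, _, _ = _meiosis(
        founders["mother"][:, 0], founders["mother"][:, 1], chroms, positions, c, rng
    )
    src, paternal_gamete, breakpoints, start_states = _meiosis(
        hap_from_gf,
        hap_from_gm,
        chroms,
        positions,
        c,
        rng,
        forced=config.forced_breakpoints or None,
        forced_chrom=config.locus.chrom,
    )

    # hap0 = the father's haplotype from the affected grandparent
    affected_idx = 0 if config.affected_grandparent == "grandfather" else 1
    father_hap0 = hap_from_gf if affected_idx == 0 else hap_from_gm
    father_hap1 = hap_from_gm if affected_idx == 0 else hap_from_gf
    state = np.where(src == affected_idx, 0, 1).astype(np.int8)

    genotypes = GenotypeTable.from_arrays(
        frame,
        grandfather=founders["grandfather"].sum(axis=1),
        grandmother=founders["grandmother"].sum(axis=1),
        father=(hap_from_gf + hap_from_gm),
        mother=founders["mother"].sum(axis=1),
    )

    pathogenic = D4Z4Allele(int(rng.integers(1, 11)), "4qA")
    normals = [
        D4Z4Allele(int(rng.integers(11, 101)), str(rng.choice(["4qA", "4qB"])))
        for _ in range(2)
    ]
    locus_s0 = (start_states.get(config.locus.chrom, 0) + affected_idx) % 2  # in hap0/hap1 terms
    truth = SimTruth(
        sites=frame,
        haplotypes={
            "grandfather": founders["grandfather"],
            "grandmother": founders["grandmother"],
            "mother": founders["mother"],
            "father": np.stack([hap_from_gf, hap_from_gm], axis=1),
        },
        father_hap0=father_hap0,
        father_hap1=father_hap1,
        fetal_paternal_state=state,
        fetal_paternal_allele=paternal_gamete,
        fetal_maternal_allele=maternal_gamete,
        breakpoints=breakpoints,
        d4z4={},
        affected_grandparent=config.affected_grandparent,
        locus=config.locus,
        _locus_start_state=locus_s0,
    )
    fetal_pat_state_at_locus = truth.paternal_state_at(config.locus.start)
    truth.d4z4 = {
        "father_hap0": pathogenic,
        "father_hap1": normals[0],
        "fetal_paternal": pathogenic if fetal_pat_state_at_locus == 0 else normals[0],
        "fetal_maternal": normals[1],
    }
    return genotypes, truth


def counts_from_dosages(
    sites: pd.DataFrame,
    maternal_dosage: np.ndarray,
    fetal_dosage: np.ndarray,
    fetal_fraction: float,
    error_rate: float,
    mean_depth: float,
    rng: np.random.Generator,
    sample_id: str = "plasma-1",
) -> pd.DataFrame:
    """Plasma allele counts for given maternal/fetal dosages.

    Per site: depth ~ Poisson(mean_depth); the expected alt fraction is
    mu = (1-f) g_m / 2 + f g_f / 2, perturbed by symmetric read error to
    mu' = mu (1 - eps) + (1 - mu) eps; alt_count ~ Binomial(depth, mu').
    Zero-depth sites are retained with zero counts.
    """
    g_m = np.asarray(maternal_dosage, dtype=float)
    g_f = np.asarray(fetal_dosage, dtype=float)
    mu = (1.0 - fetal_fraction) * g_m / 2.0 + fetal_fraction * g_f / 2.0
    mu_err = mu * (1.0 - error_rate) + (1.0 - mu) * error_rate
    depth = rng.poisson(mean_depth, size=len(g_m))
    alt = rng.binomial(depth, mu_err)
    out = sites[["chrom", "pos", "ref", "alt"]].copy()
    out["ref_count"] = (depth - alt).astype(np.int64)
    out["alt_count"] = alt.astype(np.int64)
    out["sample_id"] = sample_id
    return out[list(PLASMA_COLUMNS)]


def simulate_plasma_counts(
    genotypes: GenotypeTable,
    truth: SimTruth,
    config: SimConfig,
    sample_id: str = "plasma-1",
    fetal_fraction: float | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Maternal plasma read counts over every panel site for one sample."""
    rng = rng or _rng_for(config, 2)
    f = config.fetal_fraction if fetal_fraction is None else fetal_fraction
    return counts_from_dosages(
        genotypes.df,
        genotypes.dosages("mother"),
        truth.fetal_dosage,
        f,
        config.error_rate,
        config.mean_depth_cfdna,
        rng,
        sample_id=sample_id,
    )


def simulate_gdna_depths(
    genotypes: GenotypeTable,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-site gDNA sequencing depths for each genotyped family member."""
    rng = rng or _rng_for(config, 3)
    out = genotypes.df[["chrom", "pos"]].copy()
    for role in ("grandfather", "grandmother", "father", "mother"):
        out[role] = rng.poisson(config.mean_depth_gdna, size=len(out))
    return out
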