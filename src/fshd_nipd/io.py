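"""Reading and writing the pipeline's on-disk formats.

Genotypes travel as VCF 4.2 (GT field, one sample per family role) or as a
genotype TSV; plasma allele depths as TSV (or VCF with an AD field); panels
as BED (0-based half-open) plus a TSV carrying population frequencies;
reports and ground truth as JSON. All coordinates in TSV/VCF are 1-based.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from fshd_nipd.core import (
    PLASMA_COLUMNS,
    ROLES,
    D4Z4Allele,
    GenotypeTable,
    Locus,
    SNPPanel,
    SNPSite,
    dosage_to_gt,
    frame_to_sites,
)


# ---------------------------------------------------------------- genotypes

def write_family_vcf(genotypes: GenotypeTable, path: str | Path) -> None:
    """Write the four family members' genotypes as uncompressed VCF 4.2."""
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    df = genotypes.df
    for chrom in df["chrom"].unique():
        length = int(df.loc[df["chrom"] == chrom, "pos"].max()) + 1_000_000
        header.contigs.add(str(chrom), length=length)
    for role in ROLES:
        header.add_sample(role)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for row in df.itertuples(index=False):
            rec = vcf.new_record(
                contig=str(row.chrom),
                start=int(row.pos) - 1,
                stop=int(row.pos),
                alleles=(str(row.ref), str(row.alt)),
            )
            for role in ROLES:
                d = int(getattr(row, role))
                rec.samples[role]["GT"] = (
                    (None, None) if d == -1 else ((0, 0), (0, 1), (1, 1))[d]
                )
            vcf.write(rec)


def read_family_vcf(path: str | Path, role_map: dict[str, str] | None = None) -> GenotypeTable:
    """Read family genotypes from VCF; samples must map onto the four roles.

    ``role_map`` maps VCF sample names to roles; by default sample names are
    matched to role names case-insensitively.
    """
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if role_map is None:
            role_map = {s: s.lower() for s in samples}
        missing = set(ROLES) - set(role_map.values())
        if missing:
            raise ValueError(f"VCF samples do not cover roles: {sorted(missing)}")
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            row = {
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": rec.alts[0],
            }
            for sample, role in role_map.items():
                gt = rec.samples[sample].get("GT")
                if gt is None or any(a is None for a in gt):
                    row[role] = -1
                else:
                    row[role] = int(sum(gt))
            rows.append(row)
    return GenotypeTable(pd.DataFrame(rows))


def write_family_tsv(genotypes: GenotypeTable, path: str | Path) -> None:
    df = genotypes.df.copy()
    for role in ROLES:
        df[role] = df[role].map(dosage_to_gt)
    df.to_csv(path, sep="\t", index=False)


def read_family_tsv(path: str | Path) -> GenotypeTable:
    return GenotypeTable(pd.read_csv(path, sep="\t", dtype={"chrom": str}))


# ------------------------------------------------------------ plasma counts

def write_plasma_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts[list(PLASMA_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_plasma_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})
    missing = set(PLASMA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"plasma TSV missing columns: {sorted(missing)}")
    return df[list(PLASMA_COLUMNS)]


def read_plasma_vcf(path: str | Path, sample_id: str | None = None) -> pd.DataFrame:
    """Read plasma ref/alt depths from a single-sample VCF with FORMAT/AD."""
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) != 1:
            raise ValueError("plasma VCF must contain exactly one sample")
        sid = sample_id or samples[0]
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            ad = rec.samples[samples[0]].get("AD")
            if ad is None:
                continue
            rows.append(
                (rec.chrom, rec.pos, rec.ref, rec.alts[0], int(ad[0]), int(ad[1]), sid)
            )
    return pd.DataFrame(rows, columns=list(PLASMA_COLUMNS))


# ------------------------------------------------------------------- panels

def write_panel(panel: SNPPanel, bed_path: str | Path, tsv_path: str | Path) -> None:
    """Panel as BED (0-based half-open) plus a TSV with frequencies."""
    records = [(s, "target") for s in panel.target_sites] + [
        (s, "background") for s in panel.background_sites
    ]
    with open(bed_path, "w") as fh:
        for s, part in records:
            fh.write(f"{s.chrom}\t{s.pos - 1}\t{s.pos}\t{part}\n")
    pd.DataFrame(
        [(s.chrom, s.pos, s.ref, s.alt, s.alt_freq, part) for s, part in records],
        columns=["chrom", "pos", "ref", "alt", "alt_freq", "partition"],
    ).to_csv(tsv_path, sep="\t", index=False)


def read_panel_tsv(tsv_path: str | Path, locus: Locus, window_bp: int) -> SNPPanel:
    df = pd.read_csv(tsv_path, sep="\t", dtype={"chrom": str}, float_precision="round_trip")
    target = frame_to_sites(df[df["partition"] == "target"])
    background = frame_to_sites(df[df["partition"] == "background"])
    return SNPPanel(locus=locus, target_sites=target, background_sites=background, window_bp=window_bp)


def read_frequency_table(path: str | Path) -> list[SNPSite]:
    """Population frequencies as TSV (chrom, pos, ref, alt, alt_freq) or VCF
    with an AF INFO field."""
    path = Path(path)
    if path.suffix in (".vcf", ".bcf") or str(path).endswith(".vcf.gz"):
        sites = []
        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                if rec.alts is None or len(rec.alts) != 1:
                    continue
                af = rec.info.get("AF")
                if af is None:
                    continue
                af = af[0] if isinstance(af, tuple) else float(af)
                sites.append(SNPSite(rec.chrom, rec.pos, rec.ref, rec.alts[0], float(af)))
        return sites
    return frame_to_sites(
        pd.read_csv(path, sep="\t", dtype={"chrom": str}, float_precision="round_trip")
    )


def read_d4z4_tsv(path: str | Path) -> dict[str, D4Z4Allele]:
    """Per-haplotype D4Z4 structural calls: columns haplotype (hap0/hap1),
    repeat_count, distal_type."""
    df = pd.read_csv(path, sep="\t")
    alleles = {
        str(r.haplotype): D4Z4Allele(int(r.repeat_count), str(r.distal_type))
        for r in df.itertuples(index=False)
    }
    missing = {"hap0", "hap1"} - set(alleles)
    if missing:
        raise ValueError(f"D4Z4 table missing haplotypes: {sorted(missing)}")
    return alleles


# ----------------------------------------------------------- HMM observations

def write_observations_tsv(obs, path: str | Path) -> None:
    pd.DataFrame(
        {
            "chrom": obs.chrom,
            "pos": obs.pos,
            "b_is_alt": obs.b_is_alt.astype(int),
            "hap0_carries_b": obs.hap0_carries_b.astype(int),
            "depth": obs.depth,
            "b_count": obs.b_count,
        }
    ).to_csv(path, sep="\t", index=False)


def read_observations_tsv(path: str | Path):
    from fshd_nipd.hmm import ObservationSequence

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    chroms = df["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError(f"observation TSV spans several chromosomes: {list(chroms)}")
    return ObservationSequence(
        chrom=str(chroms[0]),
        pos=df["pos"].to_numpy(),
        b_is_alt=df["b_is_alt"].to_numpy().astype(bool),
        hap0_carries_b=df["hap0_carries_b"].to_numpy().astype(bool),
        depth=df["depth"].to_numpy(),
        b_count=df["b_count"].to_numpy(),
    )


# --------------------------------------------------------------------- misc

def write_haplotypes_tsv(haps, path: str | Path) -> None:
    df = haps.sites.copy()
    df["hap0_allele"] = haps.hap0
    df["hap1_allele"] = haps.hap1
    df.to_csv(path, sep="\t", index=False)


def write_segments_bed(segments, path: str | Path) -> None:
    with open(path, "w") as fh:
        for seg in segments.segments:
            fh.write(f"{segments.chrom}\t{seg.start - 1}\t{seg.end}\t{seg.state}\n")


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")
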