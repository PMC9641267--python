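"""FSHD1 classification and the end-to-end NIPD pipeline.

An FSHD1 allele is pathogenic when the D4Z4 array is contracted to 1-10
repeat units on a disease-permissive 4qA distal haplotype; 11+ units or a
4qB background are normal. The final prediction combines the HMM locus call
(which paternal haplotype the fetus inherited) with the D4Z4 allele linked
to that haplotype.
"""

from __future__ import annotations

import hashlib
import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

import fshd_nipd.io as nio
from fshd_nipd import __version__
from fshd_nipd.core import (
    ConsistencyError,
    ConfigurationError,
    D4Z4Allele,
    GenotypeTable,
    Locus,
    NIPDError,
    SNPPanel,
)
from fshd_nipd.fetal_fraction import estimate_per_sample, summarize_fetal_fraction
from fshd_nipd.hmm import (
    HMMParams,
    LocusCall,
    build_observations,
    call_fetal_inheritance,
    call_segments,
    forward_backward,
    viterbi,
)
from fshd_nipd.panel import panel_stats, qc_depth, select_target_snps
from fshd_nipd.phasing import phase_paternal, select_informative_snps
from fshd_nipd.simulate import (
    SimConfig,
    simulate_family,
    simulate_gdna_depths,
    simulate_plasma_counts,
    simulate_population_sites,
)

logger = logging.getLogger(__name__)

PATHOGENIC = "pathogenic"
NORMAL = "normal"
REPORT_SCHEMA_VERSION = 1


def classify_fshd1(allele: D4Z4Allele) -> str:
    """Classify one D4Z4 allele: pathogenic iff 1-10 repeats AND 4qA."""
    if 1 <= allele.repeat_count <= 10 and allele.distal_type == "4qA":
        return PATHOGENIC
    return NORMAL


def predict_fetal_status(
    locus_call: LocusCall,
    hap0_allele: D4Z4Allele,
    hap1_allele: D4Z4Allele,
) -> dict:
    """Combine the haplotype call with the hap0/hap1-linked D4Z4 alleles.

    hap0 is by construction the affected grandparent's transmitted
    haplotype, so its linked allele must classify pathogenic; anything else
    is a phasing/labeling mismatch and raises :class:`ConsistencyError`.
    """
    hap0_class = classify_fshd1(hap0_allele)
    hap1_class = classify_fshd1(hap1_allele)
    if hap0_class != PATHOGENIC:
        raise ConsistencyError(
            "hap0-linked D4Z4 allele "
            f"({hap0_allele.repeat_count}, {hap0_allele.distal_type}) classifies as "
            "normal, contradicting the affected-source haplotype labeling"
        )
    inherited = hap0_allele if locus_call.call == "hap0" else hap1_allele
    status = (
        "predicted-affected"
        if locus_call.call == "hap0"
        else "predicted-unaffected"
    )
    return {
        "locus_call": locus_call.call,
        "posterior_at_nearest_snp": locus_call.posterior,
        "nearest_snp_pos": locus_call.nearest_pos,
        "nearest_snp_distance_bp": locus_call.distance_bp,
        "predicted_status": status,
        "low_confidence": locus_call.low_confidence,
        "low_confidence_reason": locus_call.reason,
        "inherited_paternal_d4z4": {
            "repeat_count": inherited.repeat_count,
            "distal_type": inherited.distal_type,
            "classification": classify_fshd1(inherited),
        },
        "father_d4z4": {
            "hap0": {"repeat_count": hap0_allele.repeat_count,
                     "distal_type": hap0_allele.distal_type,
                     "classification": hap0_class},
            "hap1": {"repeat_count": hap1_allele.repeat_count,
                     "distal_type": hap1_allele.distal_type,
                     "classification": hap1_class},
        },
        "caveat": (
            "FSHD1 shows incomplete penetrance; a predicted-affected genotype "
            "does not determine clinical severity."
        ),
    }


class PipelineStageError(NIPDError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


@contextmanager
def _stage(name: str):
    logger.info("stage %s: start", name)
    try:
        yield
    except NIPDError as exc:
        raise PipelineStageError(name, exc) from exc
    logger.info("stage %s: done", name)


@dataclass
class NIPDReport:
    """Flat, versioned result record for one pipeline run."""

    prediction: dict
    fetal_fraction: dict
    error_rate: float
    informative_snps: int
    nearest_snp_distance_bp: int
    recombination_events: list
    qc: dict
    panel: dict
    provenance: dict
    per_sample_calls: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "prediction": self.prediction,
            "fetal_fraction": self.fetal_fraction,
            "error_rate": self.error_rate,
            "informative_snps": self.informative_snps,
            "nearest_snp_distance_bp": self.nearest_snp_distance_bp,
            "recombination_events": self.recombination_events,
            "qc": self.qc,
            "panel": self.panel,
            "per_sample_calls": self.per_sample_calls,
            "provenance": self.provenance,
        }

    def summary(self) -> str:
        p = self.prediction
        ff = self.fetal_fraction
        lines = [
            f"NIPD result: {p['predicted_status']}"
            + (" (LOW CONFIDENCE)" if p["low_confidence"] else ""),
            f"  locus call: {p['locus_call']} "
            f"(posterior {p['posterior_at_nearest_snp']:.4f} at the nearest informative SNP, "
            f"{p['nearest_snp_distance_bp'] / 1e6:.2f} Mb from the locus)",
            f"  inherited paternal D4Z4 allele: {p['inherited_paternal_d4z4']['repeat_count']} repeats, "
            f"{p['inherited_paternal_d4z4']['distal_type']} "
            f"({p['inherited_paternal_d4z4']['classification']})",
            f"  fetal fraction: median {ff['median']:.4f} "
            f"(range {ff['min']:.4f}-{ff['max']:.4f}, {ff['n_samples']} sample(s))",
            f"  sequencing error rate: {self.error_rate:.2e}",
            f"  informative SNPs: {self.informative_snps}",
            f"  recombination events: {len(self.recombination_events)}",
        ]
        for ev in self.recombination_events:
            lines.append(
                f"    {ev['from_state']} -> {ev['to_state']} at {ev['coord']} "
                f"(interval ({ev['left']}, {ev['right']}])"
            )
        return "\n".join(lines)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _infer_one_sample(obs, params, locus):
    track = forward_backward(obs, params)
    path, score = viterbi(obs, params)
    segments = call_segments(path, obs.pos, chrom=obs.chrom)
    locus_call = call_fetal_inheritance(segments, track, locus)
    return track, path, score, segments, locus_call


def run_pipeline(config: dict, outdir: str | Path | None = None) -> NIPDReport:
    """Execute panel -> fetal fraction / error rate -> phasing -> HMM ->
    classification, from simulated or on-disk inputs.

    ``config`` is a plain mapping (e.g. parsed YAML): either a ``simulate``
    section (:class:`SimConfig` fields) or an ``inputs`` section naming
    ``family_vcf``/``family_tsv``, ``plasma_tsv``, ``panel_tsv``,
    ``d4z4_tsv``, plus ``locus`` and ``window_bp``. Deterministic given
    ``seed``. All intermediate artifacts are written when ``outdir`` is
    given.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    simulate_mode = "simulate" in config
    truth = None

    if simulate_mode:
        with _stage("simulate"):
            sim_kwargs = dict(config.get("simulate") or {})
            sim_kwargs["rng_seed"] = seed
            sim = SimConfig.from_dict(sim_kwargs)
            sites = simulate_population_sites(sim)
            genotypes, truth = simulate_family(sites, sim)
            plasma = simulate_plasma_counts(genotypes, truth, sim)
            gdna_depths = simulate_gdna_depths(genotypes, sim)
            locus, window_bp = sim.locus, sim.window_bp
            affected = sim.affected_grandparent
            recomb_c = sim.recomb_rate_c
            d4z4 = {"hap0": truth.d4z4["father_hap0"], "hap1": truth.d4z4["father_hap1"]}
    else:
        with _stage("load"):
            inputs = config.get("inputs")
            if not inputs:
                raise PipelineStageError(
                    "load", ConfigurationError("config needs a 'simulate' or 'inputs' section")
                )
            locus = Locus.parse(config["locus"]) if isinstance(config.get("locus"), str) else Locus(**config["locus"])
            window_bp = int(config.get("window_bp", 5_000_000))
            affected = config.get("affected_grandparent", "grandmother")
            recomb_c = float(config.get("recomb_rate_c", 1e-8))
            if "family_vcf" in inputs:
                genotypes = nio.read_family_vcf(inputs["family_vcf"])
            elif "family_tsv" in inputs:
                genotypes = nio.read_family_tsv(inputs["family_tsv"])
            else:
                raise PipelineStageError(
                    "load", ConfigurationError("inputs must name family_vcf or family_tsv")
                )
            plasma = nio.read_plasma_tsv(inputs["plasma_tsv"])
            gdna_depths = None
            d4z4 = nio.read_d4z4_tsv(inputs["d4z4_tsv"])

    with _stage("panel"):
        if simulate_mode:
            all_sites = sites
        else:
            loaded = nio.read_panel_tsv(inputs["panel_tsv"], locus, window_bp)
            all_sites = loaded.target_sites + loaded.background_sites
        target = select_target_snps(all_sites, locus, window_bp=window_bp, maf_min=0.0)
        background = [s for s in all_sites if s.chrom != locus.chrom]
        panel = SNPPanel(locus=locus, target_sites=target,
                         background_sites=background, window_bp=window_bp)
        stats = panel_stats(panel)

    with _stage("qc"):
        qc: dict = {}
        target_keys = {(s.chrom, s.pos) for s in panel.target_sites}
        on_target = plasma[[(c, p) in target_keys for c, p in zip(plasma["chrom"], plasma["pos"])]]
        for sid, grp in on_target.groupby("sample_id"):
            verdict = qc_depth((grp["ref_count"] + grp["alt_count"]).to_numpy(), "cfDNA")
            qc[f"cfDNA:{sid}"] = {"passed": verdict.passed, "mean_depth": verdict.mean_depth,
                                  "threshold": verdict.threshold, "reason": verdict.reason}
        if gdna_depths is not None:
            gd = gdna_depths[[(c, p) in target_keys for c, p in zip(gdna_depths["chrom"], gdna_depths["pos"])]]
            for role in ("grandfather", "grandmother", "father", "mother"):
                verdict = qc_depth(gd[role].to_numpy(), "gDNA")
                qc[f"gDNA:{role}"] = {"passed": verdict.passed, "mean_depth": verdict.mean_depth,
                                      "threshold": verdict.threshold, "reason": verdict.reason}

    with _stage("fetal_fraction"):
        background_gt = genotypes.restrict_to(panel.background_sites)
        ff_estimates, eps = estimate_per_sample(plasma, background_gt)
        ff_summary = summarize_fetal_fraction(ff_estimates)

    with _stage("phase"):
        selection = select_informative_snps(genotypes, panel)
        phased = phase_paternal(selection.table, affected_source=affected)
        haps = phased.haplotypes

    with _stage("infer"):
        sample_ids = sorted(plasma["sample_id"].unique())
        f_by_sample = {e.sample_id: e.f for e in ff_estimates}
        per_sample = {}
        for sid in sample_ids:
            obs = build_observations(selection.table, haps, plasma, sample_id=sid)
            params = HMMParams(f=f_by_sample[sid], epsilon=eps.epsilon, c=recomb_c)
            per_sample[sid] = _infer_one_sample(obs, params, locus) + (obs,)
        # the final call comes from the sample with the largest fetal
        # fraction (strongest allelic signal); all calls are reported
        best_sid = max(sample_ids, key=lambda s: f_by_sample[s])
        track, path, score, segments, locus_call, obs = per_sample[best_sid]

    with _stage("classify"):
        prediction = predict_fetal_status(locus_call, d4z4["hap0"], d4z4["hap1"])

    report = NIPDReport(
        prediction=prediction,
        fetal_fraction=ff_summary,
        error_rate=eps.epsilon,
        informative_snps=selection.n_informative,
        nearest_snp_distance_bp=selection.nearest_distance_bp,
        recombination_events=[
            {"chrom": segments.chrom, "left": bp.left, "right": bp.right, "coord": bp.coord,
             "from_state": bp.from_state, "to_state": bp.to_state}
            for bp in segments.breakpoints
        ],
        qc=qc,
        panel=stats,
        per_sample_calls=[
            {"sample_id": sid,
             "fetal_fraction": f_by_sample[sid],
             "locus_call": per_sample[sid][4].call,
             "posterior": per_sample[sid][4].posterior,
             "low_confidence": per_sample[sid][4].low_confidence}
            for sid in sample_ids
        ],
        provenance={
            "seed": seed,
            "config_hash": _config_hash(config),
            "tool_version": __version__,
            "primary_sample": best_sid,
        },
    )

    if out is not None:
        with _stage("write"):
            nio.write_panel(panel, out / "panel.bed", out / "panel.tsv")
            nio.write_family_vcf(genotypes, out / "family.vcf")
            nio.write_plasma_tsv(plasma, out / "plasma.tsv")
            nio.write_haplotypes_tsv(haps, out / "haplotypes.tsv")
            track.to_frame(path).to_csv(out / "track.tsv", sep="\t", index=False)
            nio.write_segments_bed(segments, out / "segments.bed")
            if truth is not None:
                nio.write_json(truth.to_dict(), out / "truth.json")
            nio.write_json(report.to_dict(), out / "report.json")
    return report
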