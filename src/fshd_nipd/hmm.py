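"""Two-state HMM over plasma B-allele counts: which paternal haplotype did
the fetus inherit at each informative SNP?

At an informative SNP the mother is homozygous, so call B the allele she
does not carry. The father is heterozygous, with B on exactly one of his two
haplotypes. If the fetus inherited the B-carrying haplotype it is
heterozygous and fetal DNA contributes B reads at frequency f/2; otherwise
essentially no B reads appear beyond sequencing error. The hidden state is
therefore which paternal haplotype (hap0 = pathogenic, hap1 = normal) the
fetus carries; emissions are binomial in the B-read count, and transitions
between consecutive SNPs follow the Haldane map, so recombination shows up
as a state switch. Forward-backward yields per-SNP posteriors (reported as
a log10 odds track), Viterbi the segmentation and breakpoints, and the call
at the locus is the state of the nearest informative SNP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom

from fshd_nipd.core import (
    GenotypeTable,
    InferenceError,
    Locus,
    PaternalHaplotypes,
)

logger = logging.getLogger(__name__)

#: finite stand-in for log(0) emissions so a single impossible read cannot
#: propagate -inf through the recursions
LOG_FLOOR = float(np.log(np.finfo(np.float64).tiny))

STATE_LABELS = ("hap0", "hap1")


@dataclass
class HMMParams:
    """Plug-in parameters for the inheritance HMM.

    f and ε come from the fetal_fraction module (two-step workflow; they are
    not re-estimated here); c is the recombination rate in Morgans/bp
    (default 1e-8 ≈ 1 cM/Mb).
    """

    f: float
    epsilon: float
    c: float = 1e-8
    prior: tuple[float, float] = (0.5, 0.5)

    def __post_init__(self) -> None:
        if not 0.0 < self.f < 1.0:
            raise InferenceError(f"fetal fraction must be in (0,1), got {self.f}")
        if not 0.0 <= self.epsilon < 0.5:
            raise InferenceError(f"error rate must be in [0, 0.5), got {self.epsilon}")
        if self.c < 0:
            raise InferenceError(f"recombination rate must be >= 0, got {self.c}")
        if abs(sum(self.prior) - 1.0) > 1e-9 or min(self.prior) < 0:
            raise InferenceError(f"state prior must be a distribution, got {self.prior}")

    @property
    def mu_carry(self) -> float:
        """Expected B-allele read fraction when the fetus carries B."""
        half = self.f / 2.0
        return half * (1.0 - self.epsilon) + (1.0 - half) * self.epsilon

    @property
    def mu_noncarry(self) -> float:
        """Expected B-allele read fraction when the fetus does not carry B."""
        return self.epsilon


@dataclass
class ObservationSequence:
    """Position-ordered HMM observations at the informative SNPs.

    B is the allele absent from the (homozygous) mother; ``hap0_carries_b``
    says whether the father's pathogenic haplotype carries B at each site.
    """

    chrom: str
    pos: np.ndarray
    b_is_alt: np.ndarray
    hap0_carries_b: np.ndarray
    depth: np.ndarray
    b_count: np.ndarray
    n_dropped_zero_depth: int = 0

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.b_is_alt = np.asarray(self.b_is_alt, dtype=bool)
        self.hap0_carries_b = np.asarray(self.hap0_carries_b, dtype=bool)
        self.depth = np.asarray(self.depth, dtype=np.int64)
        self.b_count = np.asarray(self.b_count, dtype=np.int64)
        n = len(self.pos)
        for name in ("b_is_alt", "hap0_carries_b", "depth", "b_count"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        if n and (np.any(np.diff(self.pos) <= 0)):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.b_count < 0) or np.any(self.b_count > self.depth):
            raise ValueError("need 0 <= b_count <= depth")

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def gaps(self) -> np.ndarray:
        """Inter-site distances d_i (bp) between consecutive SNPs."""
        return np.diff(self.pos)


@dataclass
class PosteriorTrack:
    """Per-site P(hap0 | all data) with the log10 posterior-odds track."""

    chrom: str
    pos: np.ndarray
    p_hap0: np.ndarray
    log10_odds: np.ndarray
    loglik: float

    def to_frame(self, viterbi_path: np.ndarray | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.pos,
                "p_hap0": self.p_hap0,
                "log10_odds": self.log10_odds,
            }
        )
        if viterbi_path is not None:
            df["viterbi_state"] = [STATE_LABELS[s] for s in viterbi_path]
        return df


@dataclass
class Breakpoint:
    """A state switch localized to the interval (left, right] between
    flanking informative SNPs; the reported coordinate is the first SNP of
    the new segment."""

    left: int
    right: int
    coord: int
    from_state: str
    to_state: str


@dataclass
class Segment:
    start: int
    end: int
    state: str


@dataclass
class SegmentCalls:
    chrom: str
    segments: list[Segment]
    breakpoints: list[Breakpoint]


@dataclass
class LocusCall:
    """Inheritance call at the target locus from the nearest informative SNP."""

    call: str  # "hap0" | "hap1"
    posterior: float
    nearest_pos: int
    distance_bp: int
    low_confidence: bool
    reason: str | None = None


def build_observations(
    informative: GenotypeTable,
    haplotypes: PaternalHaplotypes,
    counts: pd.DataFrame,
    sample_id: str | None = None,
) -> ObservationSequence:
    """Join phased haplotypes with plasma counts into the observation stream.

    Zero-depth sites are dropped (with a log entry); they only widen the
    transition gap between their neighbours.
    """
    sites = haplotypes.sites.copy()
    sites["hap0_allele"] = haplotypes.hap0
    merged = informative.df.merge(sites, on=["chrom", "pos", "ref", "alt"], how="inner")
    sub = counts if sample_id is None else counts[counts["sample_id"] == sample_id]
    merged = merged.merge(
        sub[["chrom", "pos", "ref_count", "alt_count"]], on=["chrom", "pos"], how="inner"
    )
    if len(merged) == 0:
        raise InferenceError("no informative sites present in the plasma counts")
    chroms = merged["chrom"].unique()
    if len(chroms) != 1:
        raise InferenceError(f"informative sites span several chromosomes: {list(chroms)}")
    mo = merged["mother"].to_numpy()
    if not np.isin(mo, (0, 2)).all():
        raise InferenceError("mother not homozygous at some informative site")
    b_is_alt = mo == 0  # B = the allele the mother lacks
    hap0_allele = merged["hap0_allele"].to_numpy()
    # the father is heterozygous, so exactly one haplotype carries B
    assert np.all((hap0_allele == 1) == (1 - hap0_allele == 0))
    hap0_carries_b = np.where(b_is_alt, hap0_allele == 1, hap0_allele == 0)
    b_count = np.where(b_is_alt, merged["alt_count"], merged["ref_count"]).astype(np.int64)
    depth = (merged["ref_count"] + merged["alt_count"]).to_numpy(dtype=np.int64)
    keep = depth > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d zero-depth informative sites", n_dropped)
    order = np.argsort(merged["pos"].to_numpy()[keep], kind="stable")
    return ObservationSequence(
        chrom=str(chroms[0]),
        pos=merged["pos"].to_numpy()[keep][order],
        b_is_alt=b_is_alt[keep][order],
        hap0_carries_b=hap0_carries_b[keep][order],
        depth=depth[keep][order],
        b_count=b_count[keep][order],
        n_dropped_zero_depth=n_dropped,
    )


def emission_loglik(b_count, depth, state_carries_b, params: HMMParams) -> np.ndarray:
    """log P(b_count | depth, state) under the binomial mixture model.

    Impossible observations (rate exactly 0 with reads present) are floored
    at the log of the smallest positive double rather than -inf.
    """
    mu = np.where(state_carries_b, params.mu_carry, params.mu_noncarry)
    ll = binom.logpmf(np.asarray(b_count), np.asarray(depth), mu)
    ll = np.asarray(ll, dtype=np.float64)
    n_floored = int(np.sum(~np.isfinite(ll)))
    if n_floored:
        logger.debug("floored %d impossible emission log-probabilities", n_floored)
    return np.where(np.isfinite(ll), ll, LOG_FLOOR)


def _emission_matrix(seq: ObservationSequence, params: HMMParams) -> np.ndarray:
    """(n_sites, 2) emission log-likelihood matrix; column 0 = hap0."""
    out = np.empty((len(seq), 2))
    # state hap0 carries B exactly where hap0_carries_b; hap1 is complementary
    out[:, 0] = emission_loglik(seq.b_count, seq.depth, seq.hap0_carries_b, params)
    out[:, 1] = emission_loglik(seq.b_count, seq.depth, ~seq.hap0_carries_b, params)
    return out


def transition_prob(d_bp, c: float):
    """Haldane switch probability r(d) = (1 - exp(-2 c d)) / 2."""
    return 0.5 * (1.0 - np.exp(-2.0 * c * np.asarray(d_bp, dtype=np.float64)))


def transition_matrix(d_bp: float, c: float) -> np.ndarray:
    r = float(transition_prob(d_bp, c))
    return np.array([[1.0 - r, r], [r, 1.0 - r]])


def _transition_matrices(seq: ObservationSequence, params: HMMParams) -> np.ndarray:
    r = transition_prob(seq.gaps, params.c)
    mats = np.empty((len(r), 2, 2))
    mats[:, 0, 0] = mats[:, 1, 1] = 1.0 - r
    mats[:, 0, 1] = mats[:, 1, 0] = r
    return mats


def forward_backward(seq: ObservationSequence, params: HMMParams) -> PosteriorTrack:
    """Exact per-site posteriors P(state | all data) via scaled recursions."""
    n = len(seq)
    if n == 0:
        raise InferenceError("empty observation sequence")
    log_e = _emission_matrix(seq, params)
    # per-site scaling of emissions keeps the linear-domain recursion stable
    e_shift = log_e.max(axis=1)
    e = np.exp(log_e - e_shift[:, None])
    trans = _transition_matrices(seq, params)

    alpha = np.empty((n, 2))
    scale = np.empty(n)
    a = np.asarray(params.prior) * e[0]
    scale[0] = a.sum()
    alpha[0] = a / scale[0]
    for t in range(1, n):
        a = (alpha[t - 1] @ trans[t - 1]) * e[t]
        scale[t] = a.sum()
        alpha[t] = a / scale[t]

    beta = np.empty((n, 2))
    beta[-1] = 1.0
    for t in range(n - 2, -1, -1):
        beta[t] = (trans[t] @ (e[t + 1] * beta[t + 1])) / scale[t + 1]

    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)
    loglik = float(np.log(scale).sum() + e_shift.sum())

    p0 = np.clip(post[:, 0], np.finfo(float).tiny, None)
    p1 = np.clip(post[:, 1], np.finfo(float).tiny, None)
    log10_odds = (np.log(p0) - np.log(p1)) / np.log(10.0)
    return PosteriorTrack(
        chrom=seq.chrom,
        pos=seq.pos.copy(),
        p_hap0=post[:, 0],
        log10_odds=log10_odds,
        loglik=loglik,
    )


def viterbi(seq: ObservationSequence, params: HMMParams) -> tuple[np.ndarray, float]:
    """Most probable joint state path and its log score.

    Transition-score ties are broken toward staying in the same state (path
    continuity); a tie at the final site resolves to hap0.
    """
    n = len(seq)
    if n == 0:
        raise InferenceError("empty observation sequence")
    log_e = _emission_matrix(seq, params)
    with np.errstate(divide="ignore"):
        log_trans = np.log(_transition_matrices(seq, params))
        log_prior = np.log(np.asarray(params.prior))
    log_trans = np.maximum(log_trans, LOG_FLOOR)
    log_prior = np.maximum(log_prior, LOG_FLOOR)

    delta = np.empty((n, 2))
    psi = np.zeros((n, 2), dtype=np.int8)
    delta[0] = log_prior + log_e[0]
    for t in range(1, n):
        for i in (0, 1):
            cand = delta[t - 1] + log_trans[t - 1][:, i]
            # prefer the no-switch predecessor on exact ties
            j = i if cand[i] >= cand[1 - i] else 1 - i
            psi[t, i] = j
            delta[t, i] = cand[j] + log_e[t, i]
    last = 0 if delta[-1, 0] >= delta[-1, 1] else 1
    path = np.empty(n, dtype=np.int8)
    path[-1] = last
    for t in range(n - 1, 0, -1):
        path[t - 1] = psi[t, path[t]]
    return path, float(delta[-1, last])


def call_segments(path: np.ndarray, positions: np.ndarray, chrom: str = "") -> SegmentCalls:
    """Collapse a state path into maximal constant-state segments.

    Each state switch is a breakpoint localized to the interval
    (last SNP of the old segment, first SNP of the new segment], reported at
    the first SNP of the new segment.
    """
    path = np.asarray(path)
    positions = np.asarray(positions)
    if len(path) != len(positions):
        raise ValueError("path and positions must be aligned")
    if len(path) == 0:
        return SegmentCalls(chrom=chrom, segments=[], breakpoints=[])
    change = np.flatnonzero(np.diff(path) != 0) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change - 1, [len(path) - 1]])
    segments = [
        Segment(start=int(positions[s]), end=int(positions[e]), state=STATE_LABELS[path[s]])
        for s, e in zip(starts, ends)
    ]
    breakpoints = [
        Breakpoint(
            left=int(positions[i - 1]),
            right=int(positions[i]),
            coord=int(positions[i]),
            from_state=STATE_LABELS[path[i - 1]],
            to_state=STATE_LABELS[path[i]],
        )
        for i in change
    ]
    return SegmentCalls(chrom=chrom, segments=segments, breakpoints=breakpoints)


def call_fetal_inheritance(
    segments: SegmentCalls,
    track: PosteriorTrack,
    locus: Locus,
) -> LocusCall:
    """Locus-level inheritance call from the informative SNP nearest the locus.

    The call is that SNP's Viterbi state; its posterior and distance to the
    locus are reported. If a detected breakpoint interval spans a locus
    boundary — i.e. the state switches somewhere in the genotyping gap
    containing the locus — the call is flagged low-confidence, because the
    switch may fall on either side of the repeat array.
    """
    if len(track.pos) == 0:
        raise InferenceError("no informative sites to call from")
    dists = np.array([locus.distance(int(p)) for p in track.pos])
    i = int(np.argmin(dists))
    nearest = int(track.pos[i])
    seg_state = None
    for seg in segments.segments:
        if seg.start <= nearest <= seg.end:
            seg_state = seg.state
            break
    if seg_state is None:  # pragma: no cover - segments tile the SNP range
        raise InferenceError("nearest SNP not covered by any segment")
    posterior = float(track.p_hap0[i] if seg_state == "hap0" else 1.0 - track.p_hap0[i])
    low, reason = False, None
    for bp in segments.breakpoints:
        if bp.left < locus.start <= bp.right or bp.left < locus.end <= bp.right:
            low = True
            reason = (
                f"recombination localized to ({bp.left}, {bp.right}], which spans "
                "the locus; the switch may lie between the nearest SNP and the locus"
            )
            break
    return LocusCall(
        call=seg_state,
        posterior=posterior,
        nearest_pos=nearest,
        distance_bp=int(dists[i]),
        low_confidence=low,
        reason=reason,
    )
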