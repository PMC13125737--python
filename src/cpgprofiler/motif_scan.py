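"""Log-odds PWM scanning with exact DP p-values and CpG-overlap filtering.

A position frequency matrix (PFM) is converted to a position weight matrix
(PWM) of log2 odds against a background base distribution, after adding a
background-distributed pseudocount.  Sequences are scanned on both strands;
each window's score is assigned an exact p-value — the probability that a
random width-w word drawn i.i.d. from the background scores at least as
high — computed by dynamic programming over an integerised score grid
(``granularity`` bins per bit; the only source of p-value discretisation).
Significant hits are then filtered for overlap with CpG dinucleotides,
since a methylatable CpG inside a binding motif is what couples methylation
state to factor binding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import PFMRecord, PromoterRegion

__all__ = [
    "PWMotif",
    "MotifHit",
    "pfm_to_pwm",
    "score_pvalue",
    "scan_sequence",
    "scan_regions",
    "retain_cpg_overlapping",
    "information_content",
    "UNIFORM_BACKGROUND",
    "DEFAULT_PSEUDOCOUNT",
    "DEFAULT_GRANULARITY",
    "DEFAULT_P_THRESHOLD",
]

_BASES = "ACGT"
_COMPLEMENT = np.array([3, 2, 1, 0])  # A<->T, C<->G on integer codes

UNIFORM_BACKGROUND = np.full(4, 0.25)
DEFAULT_PSEUDOCOUNT = 0.1
DEFAULT_GRANULARITY = 1000  # integer score bins per bit
DEFAULT_P_THRESHOLD = 1e-4


@dataclass
class PWMotif:
    """A scan-ready log-odds position weight matrix."""

    motif_id: str
    motif_name: str
    probs: np.ndarray       # 4 × w, columns sum to 1
    background: np.ndarray  # length 4
    logodds: np.ndarray     # 4 × w, bits
    consensus: str

    _sf_cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.logodds.max(axis=0).sum())

    @property
    def min_score(self) -> float:
        return float(self.logodds.min(axis=0).sum())

    def int_logodds(self, granularity: int = DEFAULT_GRANULARITY) -> np.ndarray:
        """Column scores rounded to integer multiples of 1/granularity bit."""
        return np.rint(self.logodds * granularity).astype(np.int64)

    def reverse_complement(self) -> "PWMotif":
        rc_probs = self.probs[_COMPLEMENT][:, ::-1].copy()
        rc_lo = self.logodds[_COMPLEMENT][:, ::-1].copy()
        rc_cons = "".join(_BASES[_COMPLEMENT[_BASES.index(b)]] for b in reversed(self.consensus))
        return PWMotif(
            motif_id=self.motif_id,
            motif_name=self.motif_name,
            probs=rc_probs,
            background=self.background.copy(),
            logodds=rc_lo,
            consensus=rc_cons,
        )


@dataclass
class MotifHit:
    """A scored, strand-aware motif occurrence in + coordinates."""

    motif_id: str
    motif_name: str
    region: str
    start: int
    end: int
    strand: str
    score: float  # bits
    p: float
    contained_cpgs: list[int]  # indices into the region's cpg_positions
    q: float | None = None


def pfm_to_pwm(
    pfm: PFMRecord,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: np.ndarray | None = None,
) -> PWMotif:
    """Build the log-odds PWM: probs[b,j] = (counts[b,j] + pc·bg[b]) /
    (col_total + pc); logodds = log2(probs / bg)."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0 (keeps log-odds finite)")
    bg = UNIFORM_BACKGROUND.copy() if background is None else np.asarray(background, dtype=float)
    if bg.shape != (4,) or (bg <= 0).any():
        raise ValueError("background must be 4 strictly positive frequencies")
    bg = bg / bg.sum()
    counts = pfm.counts
    totals = counts.sum(axis=0)
    probs = (counts + pseudocount * bg[:, None]) / (totals + pseudocount)
    logodds = np.log2(probs / bg[:, None])
    consensus = "".join(_BASES[i] for i in probs.argmax(axis=0))
    return PWMotif(
        motif_id=pfm.motif_id,
        motif_name=pfm.motif_name,
        probs=probs,
        background=bg,
        logodds=logodds,
        consensus=consensus,
    )


def information_content(pwm: PWMotif) -> float:
    """Total relative-entropy information of the motif vs background, bits."""
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = pwm.probs * np.log2(pwm.probs / pwm.background[:, None])
    return float(np.where(pwm.probs > 0, terms, 0.0).sum())


def _score_distribution(pwm: PWMotif, granularity: int) -> tuple[int, np.ndarray]:
    """Exact distribution of the integerised score of a random background
    word: returns (offset, pmf) with pmf[i] = P(score_int = offset + i).

    DP over motif columns: each column contributes one of four integer
    scores with its background probability; the pmf is the 4-ary
    convolution across columns.
    """
    ilo = pwm.int_logodds(granularity)
    bg = pwm.background
    pmf = np.array([1.0])  # point mass at score 0
    offset = 0
    for j in range(pwm.width):
        col = ilo[:, j]
        lo, hi = int(col.min()), int(col.max())
        new = np.zeros(len(pmf) + (hi - lo))
        for b in range(4):
            shift = int(col[b]) - lo
            new[shift : shift + len(pmf)] += bg[b] * pmf
        pmf = new
        offset += lo
    return offset, pmf


def _survival(pwm: PWMotif, granularity: int) -> tuple[int, np.ndarray]:
    """Cached (offset, sf) with sf[i] = P(score_int >= offset + i)."""
    key = granularity
    if key not in pwm._sf_cache:
        offset, pmf = _score_distribution(pwm, granularity)
        sf = np.cumsum(pmf[::-1])[::-1]
        pwm._sf_cache[key] = (offset, sf)
    return pwm._sf_cache[key]


def score_pvalue(pwm: PWMotif, score_threshold: float, granularity: int = DEFAULT_GRANULARITY) -> float:
    """P(random background word scores >= threshold), exact on the score grid."""
    if not np.isfinite(score_threshold):
        raise ValueError("score threshold must be finite")
    if score_threshold <= pwm.min_score:
        return 1.0  # every word clears the threshold, independent of the grid
    offset, sf = _survival(pwm, granularity)
    t = int(np.rint(score_threshold * granularity))
    idx = t - offset
    if idx <= 0:
        return 1.0
    if idx >= len(sf):
        return 0.0
    return float(min(1.0, sf[idx]))


def _encode(sequence: str) -> np.ndarray:
    table = np.full(256, 4, dtype=np.int8)
    for i, b in enumerate(_BASES):
        table[ord(b)] = i
    return table[np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)]


def _contained_cpgs(region: PromoterRegion, start: int, end: int, overlap: str) -> list[int]:
    out = []
    for i, p in enumerate(region.cpg_positions):
        if overlap == "contain":
            ok = start <= p and p + 2 <= end
        else:  # any: at least one base of the dinucleotide inside the hit
            ok = p < end and p + 2 > start
        if ok:
            out.append(i)
    return out


def _scan_one_strand(
    pwm: PWMotif,
    codes: np.ndarray,
    granularity: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Integer window scores (positions with N get score None) and validity."""
    w = pwm.width
    n = len(codes)
    ilo = pwm.int_logodds(granularity)
    n_pos = n - w + 1
    scores = np.zeros(n_pos, dtype=np.int64)
    valid = np.ones(n_pos, dtype=bool)
    for j in range(w):
        col_codes = codes[j : j + n_pos]
        bad = col_codes >= 4
        safe = np.where(bad, 0, col_codes)
        scores += ilo[safe, j]
        valid &= ~bad
    return scores, valid


def scan_sequence(
    pwm: PWMotif,
    region: PromoterRegion,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    granularity: int = DEFAULT_GRANULARITY,
    overlap: str = "contain",
) -> list[MotifHit]:
    """Scan both strands of a region; return hits with p <= p_threshold
    sorted by (start, strand), in + coordinates.

    The − strand is scored with the reverse-complement PWM so that a match
    reported at [start, end) means the motif occurs on the reverse strand of
    that interval.  Every hit carries the CpG sites it contains (indices
    into ``region.cpg_positions``), per the requested ``overlap`` rule
    ('contain': both bases inside; 'any': at least one base).
    """
    if overlap not in {"contain", "any"}:
        raise ValueError("overlap must be 'contain' or 'any'")
    w = pwm.width
    if len(region.sequence) < w:
        return []
    codes = _encode(region.sequence)
    hits: list[MotifHit] = []
    strands = [("+", pwm), ("-", pwm.reverse_complement())]
    for strand, mat in strands:
        offset, sf = _survival(mat, granularity)
        scores, valid = _scan_one_strand(mat, codes, granularity)
        for pos in np.nonzero(valid)[0]:
            idx = int(scores[pos]) - offset
            p = 1.0 if idx <= 0 else (0.0 if idx >= len(sf) else float(min(1.0, sf[idx])))
            if p <= p_threshold:
                hits.append(
                    MotifHit(
                        motif_id=pwm.motif_id,
                        motif_name=pwm.motif_name,
                        region=region.name,
                        start=int(pos),
                        end=int(pos) + w,
                        strand=strand,
                        score=float(scores[pos]) / granularity,
                        p=p,
                        contained_cpgs=_contained_cpgs(region, int(pos), int(pos) + w, overlap),
                    )
                )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scan_regions(
    pwms: list[PWMotif],
    regions: list[PromoterRegion],
    p_threshold: float = DEFAULT_P_THRESHOLD,
    granularity: int = DEFAULT_GRANULARITY,
    overlap: str = "contain",
    add_qvalues: bool = False,
) -> list[MotifHit]:
    """Scan every motif against every region; optionally attach BH q-values
    across all (motif, position, strand) tests actually performed."""
    hits: list[MotifHit] = []
    n_tests = 0
    for region in regions:
        for pwm in pwms:
            if len(region.sequence) >= pwm.width:
                n_tests += 2 * (len(region.sequence) - pwm.width + 1)
            hits.extend(scan_sequence(pwm, region, p_threshold, granularity, overlap))
    if add_qvalues and hits:
        # BH over the full family of tests, of which only p <= threshold were kept
        ps = np.array([h.p for h in hits])
        order = np.argsort(ps)
        q = np.empty_like(ps)
        ranked = ps[order] * n_tests / (np.arange(len(ps)) + 1)
        q[order] = np.minimum.accumulate(ranked[::-1])[::-1]
        for h, qv in zip(hits, np.minimum(q, 1.0)):
            h.q = float(qv)
    return hits


def retain_cpg_overlapping(hits: list[MotifHit]) -> list[MotifHit]:
    """Keep only hits containing at least one CpG dinucleotide (order kept)."""
    return [h for h in hits if h.contained_cpgs]
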