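"""Synthetic study data with known ground truth.

Emulates the three measurement modalities of a promoter-methylation study
of a multi-transcript locus:

* **Pyrosequencing panels** — per-CpG percent methylation for a panel of
  cell lines, beta-binomially sampled around line-specific promoter means,
  with planted per-CpG multiplicative effects (>1: locally hypermethylated,
  <1: hypomethylated).
* **qPCR expression** — ΔCt per sample, monotonically coupled to the true
  promoter methylation mean plus Gaussian noise; a positive coupling slope
  makes methylation correlate positively with ΔCt, i.e. *negatively* with
  expression (transcriptional silencing by promoter methylation).
* **Promoter sequences** — random backgrounds with planted CpG islands and
  planted motif-consensus occurrences overlapping chosen CpGs.
* **qMSP cohorts** — ΔCt tables with methylated/unmethylated controls and a
  known fraction of truly methylated cases.

The default panel shape mirrors a 13-line study design with 9/20/22-CpG
promoter presets and three biological replicates.  All generators are
deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import (
    ExpressionTable,
    MethylationMatrix,
    PromoterRegion,
    QmspTable,
    cpg_label,
    find_cpg_sites,
)
from .motif_scan import PWMotif

__all__ = [
    "PanelTruth",
    "SequenceTruth",
    "generate_panel",
    "generate_promoter",
    "generate_qmsp_cohort",
    "DEFAULT_N_SAMPLES",
    "DEFAULT_N_REPLICATES",
    "CPG_PRESETS",
]

DEFAULT_N_SAMPLES = 13
DEFAULT_N_REPLICATES = 3
# promoter panel sizes of the three assayed regions (coding isoform A,
# coding isoform C, antisense lncRNA)
CPG_PRESETS = {"A": 9, "C": 20, "AS1": 22}

_BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")


@dataclass
class PanelTruth:
    """Ground truth behind one synthetic pyrosequencing + qPCR panel."""

    line_means: np.ndarray        # per-sample promoter mean methylation, percent
    cpg_effects: np.ndarray       # per-CpG multiplicative effect (1 = neutral)
    true_sample_means: np.ndarray  # per-sample mean of clipped true CpG levels, percent
    coupling_slope: float         # ΔCt per percent methylation
    coupling_noise_sd: float
    intercept: float
    read_depth: int
    overdispersion: float         # beta precision; inf disables
    planted_rho: float            # implied population Spearman target (approx)
    seed: int


@dataclass
class SequenceTruth:
    """Ground truth behind one generated promoter sequence."""

    sequence: str
    island_intervals: list[tuple[int, int]]
    planted_hits: list[tuple[str, int, str]]  # (motif_id, start, strand)
    cpg_positions: list[int] = field(default_factory=list)


def _implied_spearman(line_means: np.ndarray, slope: float, noise_sd: float) -> float:
    """Approximate population Spearman of (methylation mean, ΔCt) under the
    linear-plus-Gaussian coupling, via the Pearson → Spearman conversion
    for elliptical dependence."""
    sig = abs(slope) * float(np.std(line_means))
    if sig == 0:
        return 0.0
    pearson = sig / np.hypot(sig, noise_sd)
    rho = (6.0 / np.pi) * np.arcsin(pearson / 2.0)
    return float(np.sign(slope) * rho)


def generate_panel(
    n_samples: int = DEFAULT_N_SAMPLES,
    n_cpgs: int = CPG_PRESETS["C"],
    n_replicates: int = DEFAULT_N_REPLICATES,
    *,
    line_means: np.ndarray | None = None,
    line_mean_range: tuple[float, float] = (10.0, 90.0),
    cpg_effects: np.ndarray | None = None,
    coupling_slope: float = 0.15,
    coupling_noise_sd: float = 3.5,
    intercept: float = 4.0,
    read_depth: int = 200,
    overdispersion: float = 100.0,
    seed: int = 0,
    region_name: str = "promoter",
    transcript: str = "target",
    reference_gene: str = "GAPDH",
) -> tuple[MethylationMatrix, ExpressionTable, PanelTruth]:
    """Generate a replicated per-CpG methylation matrix and a coupled ΔCt
    expression table.

    Per (sample, replicate, CpG): the true proportion is
    ``clip(line_mean · cpg_effect, 0, 100) / 100``; a beta draw with
    precision ``overdispersion`` disperses it (``inf`` disables), and the
    observed percent is ``100 · Binomial(read_depth, p) / read_depth``.
    Per sample: ``ΔCt = intercept + coupling_slope · true promoter mean +
    N(0, coupling_noise_sd)``.  Identical seeds reproduce identical output.
    """
    if n_samples < 3 or n_cpgs < 2 or n_replicates < 1 or read_depth < 1:
        raise ValueError("need n_samples >= 3, n_cpgs >= 2, n_replicates >= 1, depth >= 1")
    rng = np.random.default_rng(seed)
    if line_means is None:
        lo, hi = line_mean_range
        line_means = rng.uniform(lo, hi, size=n_samples)
    else:
        line_means = np.asarray(line_means, dtype=float)
        if len(line_means) != n_samples:
            raise ValueError(f"line_means length {len(line_means)} != n_samples {n_samples}")
    if cpg_effects is None:
        cpg_effects = np.ones(n_cpgs)
    else:
        cpg_effects = np.asarray(cpg_effects, dtype=float)
        if len(cpg_effects) != n_cpgs:
            raise ValueError(f"cpg_effects length {len(cpg_effects)} != n_cpgs {n_cpgs}")
        if (cpg_effects <= 0).any():
            raise ValueError("cpg_effects must be > 0")

    true_pct = np.clip(line_means[:, None] * cpg_effects[None, :], 0.0, 100.0)  # sample × cpg
    true_prop = true_pct / 100.0
    true_sample_means = true_pct.mean(axis=1)

    samples = [f"line_{i + 1:02d}" for i in range(n_samples)]
    labels = [cpg_label(j) for j in range(n_cpgs)]

    obs = np.empty((n_samples * n_replicates, n_cpgs))
    index = []
    row = 0
    for i, s in enumerate(samples):
        for r in range(1, n_replicates + 1):
            p = true_prop[i]
            if np.isfinite(overdispersion):
                interior = (p > 0) & (p < 1)
                p = p.copy()
                if interior.any():
                    a = p[interior] * overdispersion
                    b = (1.0 - p[interior]) * overdispersion
                    p[interior] = rng.beta(a, b)
            k = rng.binomial(read_depth, p)
            obs[row] = 100.0 * k / read_depth
            index.append((s, r))
            row += 1
    data = pd.DataFrame(
        obs, index=pd.MultiIndex.from_tuples(index, names=["sample", "replicate"]), columns=labels
    )
    matrix = MethylationMatrix(data=data, region=region_name)

    dct = intercept + coupling_slope * true_sample_means + rng.normal(0.0, coupling_noise_sd, n_samples)
    expr = pd.DataFrame(
        dct[:, None],
        index=pd.MultiIndex.from_tuples([(s, 1) for s in samples], names=["sample", "replicate"]),
        columns=[transcript],
    )
    table = ExpressionTable(data=expr, reference_genes={transcript: reference_gene})

    truth = PanelTruth(
        line_means=line_means,
        cpg_effects=cpg_effects,
        true_sample_means=true_sample_means,
        coupling_slope=coupling_slope,
        coupling_noise_sd=coupling_noise_sd,
        intercept=intercept,
        read_depth=read_depth,
        overdispersion=overdispersion,
        planted_rho=_implied_spearman(line_means, coupling_slope, coupling_noise_sd),
        seed=seed,
    )
    return matrix, table, truth


def _random_background(rng: np.random.Generator, length: int, gc: float) -> list[str]:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return list(rng.choice(list(_BASES), size=length, p=probs))


def _island_block(rng: np.random.Generator, length: int) -> list[str]:
    """A CpG-rich block satisfying the island criterion: ~35% of positions
    start a CG dinucleotide, remainder GC-rich."""
    out: list[str] = []
    while len(out) < length:
        if rng.random() < 0.35 and len(out) + 2 <= length:
            out.extend("CG")
        else:
            out.append(rng.choice(list(_BASES), p=[0.15, 0.35, 0.35, 0.15]))
    return out[:length]


def generate_promoter(
    length: int = 1000,
    *,
    islands: list[tuple[int, int]] | None = None,
    motifs: list[PWMotif] | None = None,
    planted_hits: list[tuple[str, int, str]] | None = None,
    gc_background: float = 0.4,
    name: str = "promoter",
    strand: str = "+",
    seed: int = 0,
) -> tuple[PromoterRegion, SequenceTruth]:
    """Generate a promoter sequence with planted CpG islands and planted
    motif-consensus occurrences.

    ``islands`` are half-open spans rewritten CpG-rich; ``planted_hits``
    are (motif_id, start, strand) triples whose consensus (reverse
    complement on −) is written verbatim at the stated start.  Planted
    hits must not overlap each other.
    """
    rng = np.random.default_rng(seed)
    islands = list(islands or [])
    planted = list(planted_hits or [])
    motif_by_id = {m.motif_id: m for m in (motifs or [])}

    seq = _random_background(rng, length, gc_background)
    for s, e in islands:
        if not (0 <= s < e <= length):
            raise ValueError(f"island span ({s}, {e}) out of bounds for length {length}")
        seq[s:e] = _island_block(rng, e - s)

    spans = []
    for motif_id, start, hs in planted:
        if motif_id not in motif_by_id:
            raise ValueError(f"planted hit references unknown motif {motif_id!r}")
        w = motif_by_id[motif_id].width
        if not (0 <= start and start + w <= length):
            raise ValueError(f"planted hit {motif_id} at {start} out of bounds")
        spans.append((start, start + w, motif_id, hs))
    spans.sort()
    for (s1, e1, m1, _), (s2, e2, m2, _) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValueError(f"planted hits overlap: {m1}@[{s1},{e1}) and {m2}@[{s2},{e2})")
    for s, e, motif_id, hs in spans:
        cons = motif_by_id[motif_id].consensus
        if hs == "-":
            cons = cons.translate(_COMP)[::-1]
        seq[s:e] = list(cons)

    sequence = "".join(seq)
    region = PromoterRegion(name=name, sequence=sequence, strand=strand)
    truth = SequenceTruth(
        sequence=sequence,
        island_intervals=islands,
        planted_hits=planted,
        cpg_positions=find_cpg_sites(sequence),
    )
    return region, truth


def generate_qmsp_cohort(
    n_cases: int = 13,
    n_controls: int = 0,
    *,
    frac_methylated_cases: float = 7 / 13,
    frac_methylated_controls: float = 0.0,
    background_dct: float = 10.0,
    effect_dct: float = 4.0,
    noise_sd: float = 0.5,
    case_group: str = "case_tissue",
    control_groups: tuple[str, str] = ("control_smoker", "control_nonsmoker"),
    seed: int = 0,
) -> tuple[QmspTable, pd.Series]:
    """Generate a qMSP ΔCt cohort with known methylation labels.

    The unmethylated control (C−) sits exactly at ``background_dct``; the
    methylated control (C+) well below it.  Truly methylated samples get
    ΔCt = background − effect + N(0, noise) (signal above background:
    lower ΔCt); truly unmethylated samples get ΔCt = background +
    |N(0, noise)| (never beyond background).  The number of methylated
    cases is ``round(frac_methylated_cases · n_cases)``, so a 13-case
    cohort with fraction 7/13 plants exactly 7.  Returns the table and the
    boolean truth labels.
    """
    if n_cases == 0 and n_controls == 0:
        raise ValueError("cohort needs at least one case or control")
    if not (0 <= frac_methylated_cases <= 1 and 0 <= frac_methylated_controls <= 1):
        raise ValueError("methylated fractions must be in [0, 1]")
    if effect_dct <= 0:
        raise ValueError("effect_dct must be > 0")
    rng = np.random.default_rng(seed)

    rows = []
    labels = {}

    def _add(prefix: str, group: str, count: int, n_meth: int) -> None:
        meth = np.zeros(count, dtype=bool)
        meth[:n_meth] = True
        rng.shuffle(meth)
        for i in range(count):
            sid = f"{prefix}_{i + 1:02d}"
            if meth[i]:
                dct = background_dct - effect_dct + rng.normal(0.0, noise_sd)
            else:
                dct = background_dct + abs(rng.normal(0.0, noise_sd))
            ct_ref = 25.0 + rng.normal(0.0, 0.2)
            # dct stored explicitly so it is exact, not re-derived with fp jitter
            rows.append(
                {"sample": sid, "group": group, "ct_target": ct_ref + dct,
                 "ct_reference": ct_ref, "dct": dct}
            )
            labels[sid] = bool(meth[i])

    _add("case", case_group, n_cases, int(round(frac_methylated_cases * n_cases)))
    if n_controls:
        half = n_controls // 2
        n_meth_ctrl = int(round(frac_methylated_controls * n_controls))
        # split planted methylated controls proportionally across the two groups
        _add("ctrl_s", control_groups[0], half, min(half, n_meth_ctrl))
        _add("ctrl_n", control_groups[1], n_controls - half, max(0, n_meth_ctrl - half))
    for name, dct in (("C_plus", background_dct - 2 * effect_dct), ("C_minus", background_dct)):
        ct_ref = 25.0
        rows.append({"sample": name, "group": name, "ct_target": ct_ref + dct,
                     "ct_reference": ct_ref, "dct": dct})
        labels[name] = name == "C_plus"

    df = pd.DataFrame(rows).set_index("sample")
    table = QmspTable(data=df)
    return table, pd.Series(labels, name="methylated")


# ---------------------------------------------------------------------------
# full locus-study scenario (panel + promoter + motifs + qMSP, shared truth)
# ---------------------------------------------------------------------------

# Nested high-information consensus pair: the outer 9-mer insertion also
# creates a match of the inner 7-mer one base in, so a CpG planted inside
# the outer consensus is contained by two scanned motif occurrences.
_OUTER_CONSENSUS = "TATTCGAAT"  # CpG at offset 4
_INNER_CONSENSUS = "ATTCGAA"    # = outer[1:8], CpG at offset 3


def synthetic_pfms(counts_total: int = 100, dominant: int = 97) -> list:
    """Two synthetic CpG-containing PFMs with near-consensus columns
    (~2 bits/column), nested so one insertion yields two occurrences."""
    from .data_io import PFMRecord

    def _pfm(motif_id: str, name: str, consensus: str) -> PFMRecord:
        rest = (counts_total - dominant) / 3.0
        counts = np.full((4, len(consensus)), rest)
        for j, b in enumerate(consensus):
            counts[_BASES.index(b), j] = dominant
        return PFMRecord(motif_id=motif_id, motif_name=name, counts=counts)

    return [
        _pfm("SYN001", "synthetic_outer", _OUTER_CONSENSUS),
        _pfm("SYN002", "synthetic_inner", _INNER_CONSENSUS),
    ]


@dataclass
class LocusStudyTruth:
    """Ground truth for a full synthetic locus study."""

    planted_low: list[int]          # 0-based CpG indices with low effects
    low_effect: float
    panel: PanelTruth
    planted_hits: list[tuple[str, int, str]]
    island_intervals: list[tuple[int, int]]


def generate_locus_study(
    n_samples: int = DEFAULT_N_SAMPLES,
    n_cpgs: int = CPG_PRESETS["C"],
    n_replicates: int = DEFAULT_N_REPLICATES,
    *,
    planted_low: tuple[int, ...] = (3, 9, 15),
    low_effect: float = 0.3,
    slot: int = 30,
    read_depth: int = 200,
    seed: int = 0,
    with_qmsp: bool = True,
    **panel_kw,
):
    """Generate a coherent synthetic study of one promoter region.

    The promoter carries exactly ``n_cpgs`` CpG sites on a CpG-free A/C/T
    background: the ``planted_low`` sites sit inside a planted motif
    consensus (hence inside two nested motif occurrences), the rest are
    bare CpG dinucleotides outside any motif.  The methylation panel gives
    the planted sites a multiplicative effect of ``low_effect`` (< 1,
    locally hypomethylated) and every other site a neutral effect, so the
    low-methylation / high-TFBS-frequency candidates of the integrated
    report are exactly the planted sites.

    Returns ``(region, pfms, matrix, expr_table, qmsp_table, truth)``;
    ``qmsp_table`` is None when ``with_qmsp`` is false.
    """
    if any(not 0 <= i < n_cpgs for i in planted_low):
        raise ValueError("planted_low indices out of range")
    if slot < len(_OUTER_CONSENSUS) + 4:
        raise ValueError("slot too small for motif insertions")
    rng = np.random.default_rng(seed)
    pfms = synthetic_pfms()

    length = slot * (n_cpgs + 1)
    # G-free background: no CpG can occur outside the explicit insertions
    seq = list(rng.choice(list("ACT"), size=length, p=[0.4, 0.25, 0.35]))
    planted_hits: list[tuple[str, int, str]] = []
    for i in range(n_cpgs):
        start = slot * i + 5
        if i in planted_low:
            seq[start : start + len(_OUTER_CONSENSUS)] = list(_OUTER_CONSENSUS)
            planted_hits.append(("SYN001", start, "+"))
            planted_hits.append(("SYN002", start + 1, "+"))
        else:
            seq[start : start + 2] = list("CG")
    region = PromoterRegion(name="synthetic_promoter", sequence="".join(seq))
    if region.n_cpgs != n_cpgs:
        raise AssertionError(f"constructed {region.n_cpgs} CpGs, expected {n_cpgs}")

    effects = np.ones(n_cpgs)
    for i in planted_low:
        effects[i] = low_effect
    matrix, expr, panel_truth = generate_panel(
        n_samples,
        n_cpgs,
        n_replicates,
        cpg_effects=effects,
        read_depth=read_depth,
        seed=int(rng.integers(0, 2**31 - 1)),
        region_name=region.name,
        **panel_kw,
    )
    matrix.attach_region(region)

    qmsp = None
    if with_qmsp:
        qmsp, _ = generate_qmsp_cohort(seed=int(rng.integers(0, 2**31 - 1)))

    truth = LocusStudyTruth(
        planted_low=sorted(planted_low),
        low_effect=low_effect,
        panel=panel_truth,
        planted_hits=planted_hits,
        island_intervals=[],
    )
    return region, pfms, matrix, expr, qmsp, truth
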