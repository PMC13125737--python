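"""Fusing methylation indices with motif hits, and qMSP methylation calling.

Per-CpG integration counts, for every assayed CpG, the statistically
significant motif occurrences that directly contain the CpG dinucleotide
within their binding interval (the TFBS frequency).  A *candidate* CpG is
one with a low relative methylation index but a high TFBS frequency — the
configuration where an unmethylated, factor-accessible position may drive
transcription.

qMSP calling follows the background-control rule: the unmethylated DNA
control (C−) defines the assay's background ΔCt, and a sample is called
methylation-positive only when its signal exceeds that background — i.e.
its ΔCt lies *below* the C− ΔCt by more than a configurable guard margin
(lower ΔCt = stronger methylation-specific amplification).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import PromoterRegion, QmspTable, ValidationError, cpg_label
from .methylation_stats import RelativeIndexTable
from .motif_scan import MotifHit

__all__ = [
    "CpGReport",
    "QmspCallSet",
    "tfbs_frequency_per_cpg",
    "build_cpg_report",
    "call_qmsp",
    "cohort_rates",
]


@dataclass
class CpGReport:
    """One integrated row per CpG site."""

    cpg: str
    position: int | None
    mean_methylation_panel: float
    median_index: float
    direction: str
    tfbs_frequency: int
    candidate: bool


@dataclass
class QmspCallSet:
    """Per-sample qMSP methylation calls against the C− background."""

    calls: pd.DataFrame       # index sample; columns group, dct, call, valid
    background_dct: float
    margin: float

    def positives(self) -> list[str]:
        return list(self.calls.index[self.calls["call"] == "positive"])


def tfbs_frequency_per_cpg(
    retained_hits: list[MotifHit], region: PromoterRegion
) -> pd.Series:
    """Count, per CpG label, the retained hits whose contained CpGs include
    it; CpGs with no hits report 0."""
    counts = pd.Series(0, index=region.cpg_labels, name="tfbs_frequency", dtype=int)
    for h in retained_hits:
        if h.region != region.name:
            raise ValidationError(f"hit references region {h.region!r}, expected {region.name!r}")
        for i in h.contained_cpgs:
            counts.iloc[i] += 1
    return counts


def build_cpg_report(
    index_table: RelativeIndexTable,
    flags: pd.DataFrame,
    frequencies: pd.Series,
    region: PromoterRegion | None = None,
    mean_methylation: pd.Series | None = None,
    candidate_index_max: float = 1.0,
    candidate_freq_min: int = 1,
) -> list[CpGReport]:
    """One integrated row per CpG; candidate ⇔ median index below
    ``candidate_index_max`` and TFBS frequency at least
    ``candidate_freq_min``."""
    labels = index_table.cpg_labels
    for name, other in (("flags", list(flags.index)), ("frequencies", list(frequencies.index))):
        missing = [l for l in labels if l not in other]
        if missing:
            raise ValidationError(f"{name} missing CpG labels: {missing}")
    medians = index_table.median_index()
    if mean_methylation is None:
        # back out percent levels from indices × per-sample promoter means
        pct = index_table.indices.mul(index_table.promoter_means, axis=0)
        mean_methylation = pct.mean(axis=0)
    report = []
    for i, label in enumerate(labels):
        med = float(medians[label])
        freq = int(frequencies[label])
        report.append(
            CpGReport(
                cpg=label,
                position=(region.cpg_positions[i] if region is not None else None),
                mean_methylation_panel=float(mean_methylation[label]),
                median_index=med,
                direction=str(flags.loc[label, "direction"]),
                tfbs_frequency=freq,
                candidate=bool(med < candidate_index_max and freq >= candidate_freq_min),
            )
        )
    return report


def call_qmsp(
    table: QmspTable, margin: float = 0.0, invert_background_rule: bool = False
) -> QmspCallSet:
    """Call methylation per sample against the C− background ΔCt.

    positive  ⇔ ΔCt < ΔCt(C−) − margin (signal strictly above background);
    negative  ⇔ equality or weaker signal;
    undetected ⇔ no target amplification with a valid input control
    (counted negative);
    invalid   ⇔ no input-control amplification (excluded from rates).

    ``invert_background_rule`` flips the inequality for assays whose ΔCt
    orientation is reversed.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    background = table.background_dct
    rows = []
    for sample, rec in table.data.iterrows():
        if rec["group"] in {"C_plus", "C_minus"}:
            continue
        valid = np.isfinite(rec["ct_reference"])
        if not valid:
            call = "invalid"
        elif not np.isfinite(rec["ct_target"]):
            call = "undetected"
        else:
            above_background = (
                rec["dct"] > background + margin
                if invert_background_rule
                else rec["dct"] < background - margin
            )
            call = "positive" if above_background else "negative"
        rows.append({"sample": sample, "group": rec["group"], "dct": rec["dct"], "call": call, "valid": valid})
    calls = pd.DataFrame(rows).set_index("sample") if rows else pd.DataFrame(
        columns=["group", "dct", "call", "valid"]
    )
    return QmspCallSet(calls=calls, background_dct=background, margin=margin)


def _clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    alpha = 1.0 - conf
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def cohort_rates(
    callset: QmspCallSet, groups: list[str] | None = None, conf: float = 0.95
) -> pd.DataFrame:
    """Detected fraction per group among valid samples, with a
    Clopper–Pearson confidence interval; empty groups are omitted with a
    warning."""
    import warnings

    calls = callset.calls
    if groups is None:
        groups = list(dict.fromkeys(calls["group"]))
    rows = []
    for g in groups:
        sub = calls[(calls["group"] == g) & calls["valid"]]
        n = len(sub)
        if n == 0:
            warnings.warn(f"qMSP group {g!r} has no valid samples; omitted", stacklevel=2)
            continue
        k = int((sub["call"] == "positive").sum())
        lo, hi = _clopper_pearson(k, n, conf)
        rows.append(
            {"group": g, "n_valid": n, "n_positive": k, "rate": k / n, "ci_low": lo, "ci_high": hi}
        )
    return pd.DataFrame(rows).set_index("group")
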