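"""End-to-end drivers chaining the pipeline stages on one study.

These are the same steps the `cpgprofiler` CLI and the analysis scripts
run: simulate (or load) → relative indices + critical flags → motif scan →
CpG-overlap retention → per-CpG TFBS frequency → integrated report →
qMSP calling.
"""

from __future__ import annotations

import pandas as pd

from . import integration_qmsp, methylation_stats, motif_scan, synthetic_data
from .data_io import PFMRecord, PromoterRegion, MethylationMatrix

__all__ = ["analyze_region", "candidate_recovery"]


def analyze_region(
    matrix: MethylationMatrix,
    region: PromoterRegion,
    pfms: list[PFMRecord],
    *,
    alpha: float = 0.05,
    p_threshold: float = motif_scan.DEFAULT_P_THRESHOLD,
    pseudocount: float = motif_scan.DEFAULT_PSEUDOCOUNT,
    overlap: str = "contain",
    candidate_index_max: float = 1.0,
    candidate_freq_min: int = 1,
) -> dict:
    """Run indices → flags → scan → retain → frequencies → report for one
    promoter region; returns every intermediate alongside the report."""
    index_table = methylation_stats.relative_methylation_index(matrix)
    flags = methylation_stats.flag_critical_cpgs(index_table, alpha=alpha)
    pwms = [motif_scan.pfm_to_pwm(p, pseudocount=pseudocount) for p in pfms]
    hits = motif_scan.scan_regions(pwms, [region], p_threshold=p_threshold, overlap=overlap)
    retained = motif_scan.retain_cpg_overlapping(hits)
    freqs = integration_qmsp.tfbs_frequency_per_cpg(retained, region)
    report = integration_qmsp.build_cpg_report(
        index_table,
        flags,
        freqs,
        region=region,
        candidate_index_max=candidate_index_max,
        candidate_freq_min=candidate_freq_min,
    )
    return {
        "index_table": index_table,
        "flags": flags,
        "hits": hits,
        "retained": retained,
        "frequencies": freqs,
        "report": report,
        "report_frame": pd.DataFrame([vars(r) for r in report]).set_index("cpg"),
    }


def candidate_recovery(seed: int = 0, **study_kw) -> tuple[list[int], list[int]]:
    """Full synthetic run; returns (recovered candidate CpG indices,
    planted low-methylation CpG indices), both 0-based."""
    region, pfms, matrix, _expr, _qmsp, truth = synthetic_data.generate_locus_study(
        seed=seed, with_qmsp=False, **study_kw
    )
    result = analyze_region(matrix, region, pfms)
    candidates = [i for i, row in enumerate(result["report"]) if row.candidate]
    return candidates, truth.planted_low
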