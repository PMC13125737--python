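"""Simulate the full synthetic locus study and write its input tables.

Generates one coherent study of a 20-CpG promoter: a replicated per-CpG
methylation panel for 13 cell lines with three planted locally
hypomethylated CpGs, a methylation-coupled ΔCt expression table, the
promoter sequence with planted motif occurrences over those CpGs, the
motif set, and a 13-case qMSP cohort with 7 planted methylated samples.

Writes results/simulated/{methylation,expression,qmsp}.tsv,
promoter.fasta, motifs.jaspar, truth.json.
"""

import json
import sys
from pathlib import Path

from cpgprofiler import data_io, synthetic_data

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    region, pfms, matrix, expr, qmsp, truth = synthetic_data.generate_locus_study(seed=SEED)

    (OUT / "methylation.tsv").write_text(data_io.write_methylation_table(matrix))
    (OUT / "expression.tsv").write_text(data_io.write_expression_table(expr))
    (OUT / "promoter.fasta").write_text(data_io.write_fasta_regions([region]))
    (OUT / "motifs.jaspar").write_text(data_io.write_jaspar_pfm(pfms))
    (OUT / "qmsp.tsv").write_text(data_io.write_qmsp_table(qmsp))
    (OUT / "truth.json").write_text(json.dumps({
        "seed": SEED,
        "planted_low_cpgs": truth.planted_low,
        "low_effect": truth.low_effect,
        "planted_hits": truth.planted_hits,
        "coupling_slope": truth.panel.coupling_slope,
        "planted_rho": truth.panel.planted_rho,
    }, indent=2))

    print(f"simulated study (seed {SEED}): {len(matrix.samples)} lines x "
          f"{region.n_cpgs} CpGs x 3 replicates; planted low CpGs "
          f"{[i + 1 for i in truth.planted_low]} (effect x{truth.low_effect}); "
          f"promoter {len(region)} bp with {len(truth.planted_hits)} planted motif hits; "
          f"qMSP cohort of 13 cases -> {OUT}")


if __name__ == "__main__":
    main()
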