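"""Relative methylation indices and critical-CpG flags for the panel.

Reads results/simulated/methylation.tsv; writes results/index.tsv and
results/critical_cpgs.tsv and reports which CpGs depart from the promoter
mean (one-sample Wilcoxon across lines, BH-adjusted).
"""

from pathlib import Path

from cpgprofiler import data_io, methylation_stats

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    matrix = data_io.read_methylation_table((ROOT / "simulated" / "methylation.tsv").read_text())
    table = methylation_stats.relative_methylation_index(matrix)
    flags = methylation_stats.flag_critical_cpgs(table, alpha=0.05)

    idx = table.indices.copy()
    idx.insert(0, "promoter_mean", table.promoter_means)
    (ROOT / "index.tsv").write_text(idx.reset_index().to_csv(sep="\t", index=False, na_rep="NA"))
    (ROOT / "critical_cpgs.tsv").write_text(
        flags.reset_index().to_csv(sep="\t", index=False, na_rep="NA")
    )

    high = list(flags.index[flags["direction"] == "high"])
    low = list(flags.index[flags["direction"] == "low"])
    print(f"panel promoter means span "
          f"{table.promoter_means.min():.1f}-{table.promoter_means.max():.1f}% methylation")
    print(f"critical CpGs: {len(high)} relatively hypermethylated {high}, "
          f"{len(low)} relatively hypomethylated {low}")


if __name__ == "__main__":
    main()
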