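"""Scan the promoter for significant, CpG-overlapping motif occurrences.

Reads results/simulated/{promoter.fasta,motifs.jaspar}; writes
results/hits.tsv and results/hits.bed; reports how many significant hits
were found and how many survive the CpG-containment filter.
"""

from pathlib import Path

from cpgprofiler import data_io, motif_scan

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    (region,) = data_io.read_fasta_regions((ROOT / "simulated" / "promoter.fasta").read_text())
    pfms = data_io.read_jaspar_pfm((ROOT / "simulated" / "motifs.jaspar").read_text())
    pwms = [motif_scan.pfm_to_pwm(p) for p in pfms]

    hits = motif_scan.scan_regions(pwms, [region], p_threshold=1e-4, add_qvalues=True)
    retained = motif_scan.retain_cpg_overlapping(hits)

    rows = [{
        "motif_id": h.motif_id, "motif_name": h.motif_name, "region": h.region,
        "start": h.start, "end": h.end, "strand": h.strand,
        "score_bits": round(h.score, 4), "p": h.p, "q": h.q,
        "contained_cpg_labels": ",".join(region.cpg_labels[i] for i in h.contained_cpgs),
    } for h in hits]
    (ROOT / "hits.tsv").write_text("# scan p_threshold=0.0001 overlap=contain\n"
                                   + data_io.write_report(rows))
    (ROOT / "hits.bed").write_text(data_io.hits_to_bed(hits))

    ics = {p.motif_id: round(motif_scan.information_content(p2), 1)
           for p, p2 in zip(pfms, pwms)}
    print(f"scanned {len(pwms)} motifs (information content {ics}) over "
          f"{len(region)} bp / both strands at p <= 1e-4: {len(hits)} significant hits, "
          f"{len(retained)} containing a CpG dinucleotide")


if __name__ == "__main__":
    main()
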