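# Methods

This note records the models, parameter choices and numerical conventions
behind cpgprofiler, and what the synthetic-data generator does and does not
emulate.

## Data model and coordinates

All intervals are 0-based, half-open internally; 1-based labels
(`CpG_1`, …) appear only in reports. A CpG site is the position of its C on
the supplied (+) orientation; methylation is treated as strand-symmetric, so
no separate − strand site list is kept (an antisense transcript only changes
the `strand` annotation of a region, never its coordinates). Tables are
tab-separated UTF-8 with `NA` for missing; motif hits additionally serialise
to BED6 (score = −10·log10 p, capped at 1000).

Methylation percentages outside [0, 100] are rejected at parse time with the
offending cell named. Replicates are aggregated by median per (sample, CpG)
before any summary — medians are what replicated pyrosequencing panels are
usually reported as — with mean available as an option; a cell missing in
more than half of a sample's replicates is reported missing for that sample.

## Relative methylation index and critical CpGs

The index divides each CpG's (replicate-aggregated) percent methylation by
the mean over the same CpG set in the same sample. Using the same
aggregated values and the same CpG set for numerator and denominator makes
the per-sample mean of indices exactly 1 on complete data (asserted to
1e-12); the index is also invariant to scaling all of a sample's values,
which is what removes between-line global-methylation differences. Samples
with a zero promoter mean (fully unmethylated) yield missing indices with a
warning, never infinities.

Criticality is a panel-level statement: per CpG, a two-sided one-sample
Wilcoxon signed-rank of the indices against 1 across samples, with direction
from the median index and `neutral` when p ≥ α (default 0.05) or fewer than
3 usable samples. Up to 13 non-zero differences the full 2^n sign-flip
distribution is enumerated on midranks (ties exact); beyond that the
tie-corrected normal approximation is used. Benjamini–Hochberg q-values
across the tested CpGs are reported alongside raw p.

An interpretation worth making explicit: because the index is
self-normalising, planting *high* effects at some CpGs necessarily pushes
every other CpG's index below 1 (neutral index = 1/mean(effects)). Flags in
the unplanted direction on such panels are therefore mathematically correct
statements about the index, not errors of the test; recovery of planted
effects is consequently evaluated direction-specifically (a planted ×1.5 CpG
counts as found only when flagged `high`, and only spurious `high` flags
count as false).

## Group contrasts

Two groups: Mann–Whitney, exact by full enumeration of the C(n, n_a) group
assignments on midranks when both sizes ≤ 8 — the two-sided p is the
probability of a U at least as far from n_a·n_b/2 as observed (the
permutation distribution is symmetric about that centre even under ties) —
and scipy's tie/continuity-corrected normal approximation above. Three or
more groups: tie-corrected Kruskal–Wallis (requesting it with two groups is
an error that points to Mann–Whitney; all-constant input returns H = 0).
The demethylating-agent contrast reports, per CpG, the difference of medians
(treated − vehicle) with a Mann–Whitney p over replicate values, plus
ΔΔCt = median treated ΔCt − median vehicle ΔCt, negative meaning
re-expression.

## Expression analysis

Tertile cutoffs are the 33rd/66th percentiles by linear interpolation
between order statistics (h = (n−1)p + 1, the numpy default). The preset
pair (9.083, 15.308) is kept as opaque constants for classifying against the
originally published boundaries; boundary values are inclusive toward the
extreme classes (ΔCt ≤ low cutoff → high expression, ΔCt ≥ high cutoff →
low), with `high` winning if the cutoffs coincide.

Spearman correlation uses midranks; the two-sided p is an exact permutation
enumeration for n ≤ 9 and the t approximation t = ρ·√((n−2)/(1−ρ²))
otherwise. Every result carries both orientations (ρ vs ΔCt and its
negation vs expression) because a positive ρ against ΔCt *is* a negative
methylation–expression association; collapsing the two signs silently is the
classic error in this analysis.

Clustering is scipy complete linkage on Euclidean distances over raw ΔCt
profiles — no transformation or per-gene normalisation, matching how such
panels are typically clustered — with the tree cut by `maxclust` and
serialised as Newick. Missing cells are a hard error (no silent imputation).

## Motif scanning

PWM construction: probs = (counts + pc·bg)/(total + pc) with pseudocount
pc = 0.1 distributed by the background (uniform by default, or estimated
from the scanned sequence on request), log-odds in bits. Significance is an
*exact* p-value: the distribution of a random background word's score is
computed by dynamic programming after rounding each column's log-odds to
integer multiples of 1/1000 bit; the DP is exact on that grid, so the grid
(1000 bins/bit) is the only source of discretisation error, verified against
exhaustive 4^w enumeration. A threshold at or below the minimum score
returns p = 1 by definition, independent of the grid.

Both strands are scanned (the − strand via the reverse-complement PWM, with
its own score distribution so non-symmetric backgrounds remain exact),
reported in + coordinates; windows containing N are skipped; overlapping and
duplicate occurrences are all reported (no greedy merging — the integration
counts per occurrence). The default significance threshold is p ≤ 1e-4,
recorded in output headers; optional BH q-values are computed over the full
family of (motif, position, strand) tests performed, not only the reported
hits. CpG containment defaults to both bases of the dinucleotide inside the
hit interval (`any` relaxes to one base), because a methylatable cytosine
*within* the binding footprint is the mechanistically interesting case.

## Integration and qMSP

The per-CpG report joins the median index, the criticality direction, the
panel mean methylation and the TFBS frequency (count of retained hits
containing the CpG; the sum over CpGs equals the sum of per-hit contained
CpG counts). A candidate CpG has median index < 1.0 and TFBS frequency ≥ 1;
both thresholds are explicit configuration because the underlying pattern —
low local methylation where binding sites cluster — is qualitative.

qMSP calling: the single required C− (unmethylated control) row defines the
background ΔCt; positive ⇔ ΔCt < background − margin, with margin
defaulting to 0 but configurable as a guard band for baseline technical
variation. Lower ΔCt means stronger methylation-specific amplification;
an `invert_background_rule` flag exists for assays with the opposite
orientation rather than guessing from data. Samples without target
amplification but with a valid input control are `undetected` and count
negative; samples without input-control amplification are invalid and are
excluded from rates. Rates carry Clopper–Pearson 95% intervals.

## CpG islands

The literature's loose "≥ 200 nt with high CpG content" phrasing is not
operational; the finder implements the standard sliding-window rule: every
200-nt window with GC ≥ 0.5 and CpG observed/expected ≥ 0.6
(obs/exp = n_CpG·w/(n_C·n_G)), passing windows merged, merged intervals ≥
200 nt kept. All four thresholds are configurable; passing `gc_min=0.6`
gives the stricter literal variant. Verified against an exhaustive
all-windows oracle.

## Synthetic data: what it emulates, and what it does not

`generate_panel` draws, per (sample, replicate, CpG), a beta-dispersed
proportion around clip(line_mean·cpg_effect)/100 (beta precision 100 by
default; ∞ disables) and then a binomial with the pyrosequencing read depth
(default 200, a typical per-CpG depth); the observed value is the binomial
fraction in percent. ΔCt is linear in the sample's true promoter mean plus
Gaussian noise. Defaults mirror the motivating study's shape: 13 lines,
3 replicates, CpG panel presets of 9/20/22 sites, line means uniform on
10–90%, coupling slope 0.15 ΔCt per percent with noise sd 3.5 — a
combination whose implied population Spearman (vs ΔCt) is ≈ 0.7, in the
range such panels report. A positive slope makes methylation correlate
*positively* with ΔCt, i.e. negatively with expression.

`generate_promoter` plants CpG-rich island spans and verbatim motif-consensus
insertions (reverse-complemented on −) into a random background of chosen GC
content. The full `generate_locus_study` scenario instead builds a G-free
background so that the promoter's CpG sites are exactly the 20 planted ones:
three sit inside a planted 9-mer consensus that nests a 7-mer motif (so each
planted CpG lies within two scannable occurrences) and carry a ×0.3
methylation effect; the rest are bare CpG dinucleotides. This makes the
candidate set construction-determined. `generate_qmsp_cohort` places the C−
control exactly at the background ΔCt, truly methylated samples one effect
size (default 4 ΔCt) below it, and truly unmethylated samples at or above
it; the planted positive count is round(fraction·n), so 13 cases at 7/13
plant exactly 7. ΔCt values are stored explicitly alongside the Ct pair so
noise-free fixtures are exact, not subject to float re-derivation.

What passing on these data does *not* show: real pyrosequencing has
sequence-context biases, bisulfite conversion failure, and correlated
neighbouring CpGs, none of which are modelled beyond beta-binomial
dispersion; real promoters have motif matches at all information contents
and overlapping true sites, whereas the scenario plants well-separated
high-information consensi; real qMSP baselines drift, which the margin
parameter acknowledges but the generator idealises. Recovery results
therefore validate the computation, not assay performance on tissue.

## Problem sizes and determinism

Everything is seeded through `numpy.random.default_rng`; identical
configuration and seed reproduce byte-identical TSVs. The recovery analyses
use 100–200 replicate simulations (12–13 samples each) and 50 motif plants
in 1-kb backgrounds — sizes at which the construction-determined outcomes
are stable across seeds while the whole suite runs in seconds.

## Known limitations

No DMR calling across genomic windows (only assayed CpG panels), no motif
discovery or JASPAR retrieval, no raw-trace or FASTQ handling, no array
(450K/EPIC) input, and no heatmap rendering (the cluster tree serialises to
Newick instead). The Wilcoxon-based panel criticality test is one defensible
choice among several (per-line replicate tests would be the alternative when
replicate counts are large); it is configurable at the α level only.
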