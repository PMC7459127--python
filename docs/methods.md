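# Methods

This note documents the models, conventions and numerical choices behind
`mobiscan`, and what the synthetic cohorts do and do not show about real
data.

## Coordinates and containers

All in-memory positions are 0-based half-open; conversion to the 1-based
inclusive convention of GFF3 and the emitted TSV tables happens exactly
once, in `mobiscan.io`. A breakpoint `pos` is the reference base
immediately left of the insertion point. For a non-reference insertion
with a target-site duplication (TSD) of `t` bp the left- and right-
junction breakpoints of one event are `t` bp apart (the TSD belongs to
both flanks); for a reference insertion the two junctions flank the
element's reference span. The genotype matrix is held as a dense
loci × accessions array of {P, A, H, M} with parallel presence/absence
supporting-read counts. FASTQ qualities are carried through I/O but are
inert: all calling is read-count based.

## End library

Elements longer than 150 bp contribute a prefix (L) and suffix (R) end;
shorter elements one `whole` end. Redundancy collapse is greedy over ends
sorted by (length desc, te_id asc, side asc): a candidate is dropped iff
it aligns to an already-kept representative at ≥ 90 % identity over ≥ 75
aligned columns, on either strand. The criterion is applied with exact
affine-gap Smith–Waterman (match +1, mismatch −2, gap open −4, gap extend
−1; a gap of length L costs 4 + (L−1)) rather than a BLAST e-value
heuristic — deterministic and dependency-free, with identity defined as
matches over aligned columns. Both-strand comparison is the default
because TE ends occur in either orientation; a flag disables it.
Consequences worth knowing: the two ends of an element shorter than
~300 bp overlap and usually collapse to one representative, after which
only one junction of such insertions is discoverable — the locus is still
found through the remaining end.

## Discovery

A read is a junction read when an ungapped match to a library end covers
≥ 20 read bases at ≥ 95 % identity, **reaches the terminal base of the
end that forms the junction** (the first base of an L end, the last of an
R end, either for `whole`), and leaves ≥ 30 contiguous unmatched bases on
exactly one side — the genomic flank. Matching is exact-15-mer
seed-and-extend with a seed stride of 6, which guarantees a seed inside
any error-free 20-bp match; both read orientations are searched and the
best-scoring end wins (ties: library order, then forward orientation).

Flanks are placed on the reference by the same seed-and-extend search on
both strands; a placement is accepted only when exactly one location
attains the best match count, no second location scores within 95 % of
it, and the best covers the flank at ≥ 95 % identity. The 95 %-of-best
second-hit rule is this package's explicit stand-in for the read-mapper
uniqueness filtering used in short-read pipelines.

Breakpoints pooled over all accessions are single-linkage clustered
within (chrom, te_id, junction side) at |Δpos| ≤ 15 bp; the locus
position is the median member position (lower middle on even counts), so
the locus set is invariant to read input order. A locus is **Ref** when
the reference sequence adjacent to the breakpoint (opposite the mapped
flank) matches the correspondingly oriented element terminus at ≥ 90 %
identity over ≥ 50 bp; the full-element alignment then delimits the
reference TE span (exact occurrence is tried first, a local alignment
bounded by twice the element length as fallback). N never counts as a
match anywhere, so N-rich sequence fails these thresholds rather than
passing vacuously.

## Genotyping

Templates per locus: non-Ref presence = 150 bp of reference flank joined
to 150 bp of the oriented element terminus; non-Ref absence = the 300-bp
reference window across the insertion point. Ref presence = the reference
junction window itself (the element is in the assembly); Ref absence =
the excision joint with one TSD copy removed — the largest `t ≤ 12` with
identical 5′/3′ copies is excised together with the span, so the template
matches a true pre-insertion haplotype exactly. Loci whose Ref span could
not be delimited get presence templates only and are effectively
genotyped presence-vs-missing. Templates truncated at a contig edge below
2 × 20 bp raise an error.

A read supports an allele when it crosses the template's junction point
with ≥ 20 *matched* bases on each side at ≥ 95 % identity over the
overlap; reads qualifying for both alleles of one locus are discarded as
uninformative. Because the matched-bases requirement exceeds any TSD
length (≤ 12), flank-only reads of carriers cannot fake absence support.
Calling needs a single read per allele: stringency is deliberately
deferred to the filter cascade's singleton-support rule, and H requires
≥ 1 read on each allele with no binomial test — the cohorts modelled here
are near-homozygous, and read depth per haplotype (~5×) is too low for a
meaningful test.

## Filter cascade

Applied in order, with strict inequalities exactly as specified: missing
fraction > 0.5 (over all accessions); heterozygote fraction > 0.41 (over
non-missing calls — the denominator choice is ours, documented because it
is ambiguous); single-carrier loci with < 3 presence reads; then end-pair
merging. Two loci merge when they share the element, lie on opposite
junction sides, and sit within 25 bp (non-Ref; covers TSDs plus jitter)
or flank one reference span (Ref). Merged genotypes join as
(P,P)→P, (A,A)→A, any H→H, (x,M)→x, and (P,A)→M: a true heterozygote
should show consistent evidence at both ends, so a cross-end conflict is
treated as an artifact, not a heterozygote. Read counts are summed and
the leftmost position kept. The `FilterReport` identity
`final = initial − missing − het − lowsupport − merged` is checked on
every run, and the cascade is idempotent.

## Population analytics

Carrier frequency is (P+H)/(P+A+H) — a heterozygote carries the
insertion. Class boundaries on exact fractions: fixed iff freq = 1;
high 0.70 < f < 1; median 0.30 < f ≤ 0.70; low f ≤ 0.30. Differential
fixation between ordered groups (g1, g2) requires freq(g1) ≥ 0.90 and
freq(g2) ≤ 0.10; heterogeneous loci have a pairwise frequency spread
> 0.5, so every differential-fixed locus is heterogeneous. Gene-proximity
annotation is a single category per breakpoint with precedence
CDS > intron > upstream > downstream > intergenic; up/downstream are the
500-bp windows adjacent to the gene span, strand-aware, boundary
inclusive at 500 bp; overlapping genes resolve by precedence, then
distance, then gene id. Report rounding follows the printed-table
conventions: densities to integers, averages and percentages half-up to
one decimal.

## Population genetics

Loci with 0.2 ≤ freq ≤ 0.8 (inclusive) are encoded 1/0/? with H → 1; the
diploid dosage (P = 2, H = 1, A = 0) is retained alongside because the
F<sub>ST</sub> estimator needs observed heterozygosity — the binary
encoding alone would destroy it. Distances are mean pairwise character
differences over mutually called loci (error when a pair shares none).
Neighbor joining is the standard Saitou–Nei agglomeration with the Q
criterion; ties break on the lexicographically smallest label pair (each
cluster labelled by its smallest leaf), and a negative branch length is
clamped to zero with the deficit moved to the sister branch so the pair
sum is preserved. Full least-squares branch re-fitting is not performed;
on additive matrices plain NJ is already exact, which the tests verify
directly. PCA mean-imputes missing cells per locus, centers, scales by
√(p̄(1−p̄)) (the SNP-dosage normalization; a flag disables scaling), and
eigen-decomposes the accession covariance; signs are fixed by making each
component's largest-magnitude coordinate positive, and percent variance
is taken over positive eigenvalues. F<sub>ST</sub> implements the Weir &
Cockerham (1984) variance components a, b, c per biallelic locus for two
populations with observed heterozygosity, reported as the ratio of sums
Σa/Σ(a+b+c); loci with fewer than two called accessions in either group
are skipped, and an all-monomorphic locus set is an error. With few loci
and small groups the null distribution of the ratio-of-sums estimator is
wide — values like −0.1 between undifferentiated groups of five are
ordinary sampling noise, not a defect.

## Synthetic cohorts

The generator emulates the study conditions: a uniform-random backbone
(two chromosomes, 100 kb total by default), a TE library spanning TIR
(Pong, CACTA, Tc1/Mariner), Helitron, LTR (Copia, Gypsy), SINE and LINE
families with per-family TSD lengths (0 for Helitron-like, 2–8
otherwise), 20 accessions in four morphotypes (6/5/5/4 — the cohort's
four large groups scaled down), 60 insertion loci spanning the
low/median/high/fixed spectrum plus 12 differential-fixed contrasts
(0.95 vs 0.05), ~10× uniform single-end 100-bp reads, a 1 % default
substitution error rate (set to 0 where an exactness property is
measured), and a 5 % heterozygote rate among carriers. Insertion sites
are rejection-sampled so every flank 15-mer is unique genome-wide,
guaranteeing unique flank mapping; a "hard mode" flag plants a duplicated
segment to exercise the multi-mapping discard path instead. One RNG
stream per stage derives from the master seed, so changing one stage's
parameters leaves the others' draws intact and all outputs are
deterministic under the seed.

Two deliberate generator choices: carrier counts are realized **exactly**
(`round(freq · n_group)` carriers drawn without replacement) rather than
by Bernoulli sampling, so planted frequency classes and differential
contrasts survive group sizes of four to six; and family copies diverge
15 % per copy from their consensus (~26 % pairwise) so ends of distinct
copies never collapse as redundant. Even so, terminal windows of family
copies can be near-identical by chance; junction reads with short TE
overlap then tie between homologous elements, and a locus can appear
twice keyed to the sister element at the same position. This is the
family-homology ambiguity every split-read TIP caller carries and the
reason precision is assessed positionally.

What the simulations do **not** model: indels and quality-profile errors,
GC and coverage bias, repeat-rich backbones (unique mapping is guaranteed
by construction, except in hard mode), paired-end evidence, nested or
truncated insertions, and genome-scale data volumes. Passing tests
therefore demonstrate correctness of the algorithms under clean
conditions and calibrated behaviour under uniform substitution noise, not
performance on real resequencing data.

## Problem sizes

Unit tests run on 30 kb / 6-accession cohorts; the end-to-end recovery
properties on the default 100 kb / 20-accession cohort across five seeds
(≈ 8 s per seed); estimator properties on matrices of up to 13 taxa, 400
loci and 400 diploids. The acceptance script re-runs the default cohort
once plus the estimator checks, a few seconds in total.

## Known limitations

Single-end junction evidence only (no discordant read pairs); locus
strand is not recorded; Ref loci without a delimitable span cannot show
absence evidence; the heterozygosity threshold 0.41 is taken as given
rather than re-derived; chi-square analyses drop empty rows/columns with
a warning rather than pooling.
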