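# Methods

## The typing problem

In a duplicated MHC family where gene conversion homogenises flanking
sequence, alleles cannot be assigned to loci. A diploid individual carrying
haplotypes with `g1` and `g2` gene copies therefore presents as an
unordered *set* of up to `g1 + g2` distinct amplicon sequences, each backed
by some number of reads. Typing reduces to three problems this package
solves in sequence: recovering each individual's set of true sequences from
noisy reads (calling), validating sequences population-wide against
artefacts (cataloguing), and inferring the haplotype copy-number structure
that explains the distribution of set sizes (copy-number model).

## Allele calling

Reads from one individual are grouped by identical sequence and visited in
decreasing group size (ties broken lexicographically — the order is then
fully deterministic). A group joins the cluster whose running plurality
consensus it matches with mismatch fraction ≤ `max_mismatch_frac` (default
0.02) and no alignment gap run longer than `max_gap` (default 6 nt);
equal-length comparisons are Hamming, unequal lengths go through a global
edit-distance alignment (edlib) whose path is projected onto the consensus
coordinates. Each cluster's consensus is then called per column at a 75%
threshold; a column where no base reaches the threshold is ambiguous, and
the cluster is split by the bases at the first ambiguous column,
recursively. This is what separates two co-occurring alleles that differ at
a single position: they co-cluster under the 2% ceiling, produce a ~50/50
column, and split cleanly when both are well represented. Sequencing errors
(~0.2% per base) never approach the 25% needed to darken a column.

A contig is screened as a PCR chimera when its consensus is exactly a
single-crossover hybrid of two deeper co-occurring contigs at some
breakpoint *and* its depth is below `chimera_depth_frac` (default 0.5)
times the shallower parent — chimeras are clearly under-represented
relative to their templates. The depth condition operationalises an
otherwise qualitative rule; 0.5 is configurable. A deep hybrid is *not*
flagged and is left to population-level validation.

Validation pools identical consensi across individuals: **confirmed**
requires ≥ 2 individuals and ≥ 12 reads (summed across individuals by
default; `min_reads_mode="per_individual"` requires one individual alone to
reach the floor — the read-count scope of the rule is ambiguous and both
readings are provided); **provisional** requires a single individual,
≥ 12 reads, and a depth at least `singleton_min_frac` (default 0.25) of the
mean depth of co-occurring contigs — the operationalisation of "not
blatantly below co-occurring alleles". Sequences whose exon translation
(frame begins after the 7 intronic nucleotides) contains a stop codon are
catalogued but quarantined as `nonfunctional_stop`. Genotyping then accepts
only 100% full-length matches between contig consensi and the catalog;
near-misses are reported separately, never rescued. Individuals with fewer
than 25 total reads are discarded.

## Demultiplexing

Dual 4–8-nt tags at pairwise edit distance ≥ 3 identify individuals.
Decoding is minimum-Hamming over each tag's own length with a default
tolerance of one mismatch; ties are rejected as ambiguous. Because tag
lengths vary, a short tag followed by the amplification primer could
impersonate a longer foreign tag, so every candidate must also be followed
by ≥ 70% identity to the primer — a loose context check, not a scored
alignment. Trimming is by fixed offset (tag length + primer length) at both
ends. With these rules no misassignment was observed against the truth
table in any synthetic run; double substitution errors inside one tag can
in principle still cross to a distance-3 neighbour, at a per-read
probability of order 10⁻⁵ at the default error rate.

## Synthetic data: what it emulates, what it does not

The generator reproduces the features the pipeline's thresholds act on:
a pool of unique stop-free 277-nt amplicons descended from a common
ancestor along a Kingman coalescent genealogy (per-site substitution rate
calibrated so expected pairwise divergence equals `divergence`, default
0.18 ≈ the π ~ 0.11–0.12 typical of MHC exon-2 repertoires); diploids
drawn from haplotype classes `p` with per-slot sharing `s`; lognormal
per-individual depth (mean 284, SD 284, truncated by rejection to
[29, 2741]); i.i.d. substitution errors over the whole read (0.2% default —
the true platform error of the emulated run is unknown; this is a
configuration choice); and single-crossover chimeras at a uniform
breakpoint between two of the individual's templates (2% of reads by
default). Two genealogy switches shape the site-frequency spectrum:
`deep_split` inserts a long root branch between two balanced clades,
producing the intermediate-frequency variants of balancing selection
(Tajima's D well above 1), and `selected_codons`/`selection_boost` raise
the substitution rate at the first two positions of chosen codons with a
nonsynonymous-preferring base choice, producing dN ≫ dS in the masked
partition only.

Not emulated: homopolymer indel error (the dominant 454 artefact class —
the pipeline's gap rule is exercised by constructed fixtures instead),
quality-score information (constant Q30 placeholders; the pipeline never
reads qualities), multi-crossover chimeras, primer-site mutation dropout
(null alleles), and contamination. Passing the synthetic end-to-end tests
therefore demonstrates correctness of the clustering/validation logic under
substitution noise and single-crossover chimerism, not robustness to indel
noise or allele dropout on real data.

## Polymorphism statistics

Columns containing a gap or non-ACGT symbol are excluded from S, η, π and
k (per-site complete deletion). η counts `(distinct bases − 1)` per
column; π = k / (number of included sites). Tajima's D uses the canonical
coefficients; it is reported as undefined (`None`) when S = 0 or when the
variance expression degenerates (e.g. n = 3 with a single variable site).
Significance uses the standard beta-distribution approximation on
`[Dmin, Dmax]`. Sliding windows are 1-based inclusive, default 24 nt by
3 nt. Both the global D and the mean of window D values are reported where
relevant, since "average D" is ambiguous between the two. Synonymous
alleles collapse to protein classes named after the most common member
(ties by name).

## Selection tests

Modified Nei–Gojobori counting weights the transition at each codon
position `2R` against `1` for each transversion (`R = 0.5` recovers the
unmodified equal-weight method). Changes *to* stop codons are counted as
nonsynonymous rather than excluded, which preserves N + S = 3 per codon
exactly for any R; at the divergences involved the difference from
excluding them is far below the bootstrap noise. Observed differences
average over all orderings of the differing positions, skipping orderings
that pass through a stop codon (all orderings are used if every one is
blocked). Codons containing gaps or ambiguity in either sequence of a pair
are dropped (pairwise deletion). `R` defaults to the Kimura two-parameter
transition/transversion ratio estimated from the alignment, overridable.
Rates are means over all sequence pairs; standard errors come from
bootstrap over codon sites within each partition (1000 replicates,
seeded); the Z-test is one-tailed against the normal.

The PBR mask ships as an editable data file of 1-based codon indices
(`data/pbr_codons.txt`), the peptide-contact residues of the human class II
crystal structure assumed to map one-to-one onto the 90-codon exon-2
alignment starting at residue 1. The true residue-to-alignment offset for
any non-model species is uncertain by a few codons; partition rates in real
data shift accordingly, which is why the mask is data, not code.

The Phi statistic is the mean pairwise incompatibility (cycle in the
state-intersection graph; 0/1 scoring) among parsimony-informative sites
within `window` informative sites of each other. Recombination makes
nearby sites share genealogies, so evidence is a *low* observed Phi
relative to the site-order permutation null; p-values are reported both by
permutation and by a normal approximation using the exact permutation mean
and variance (derived from the incompatibility matrix moments; verified
against the permutation sample). Note that when `window` is at least the
number of informative sites the statistic equals its null mean and the
test has no power — window sizes around 10 informative sites are effective
on exon-2-sized alignments.

## Copy-number model

With haplotype classes pairing at random, the distinct-allele count is
`a = g1 + g2 − X`, `X ~ Binomial(min(g1, g2), s)`, marginalised exactly.
The fit maximises the multinomial likelihood by deterministic simplex-grid
refinement (coarse 0.05 lattice, four 5-fold local refinements, final
resolution 4 × 10⁻⁴; no gradients, no randomness). Sharing is searched on
`[0, s_max]`, default 0.2: the likelihood possesses a mirror mode in which
extreme sharing (s ≈ 0.5–0.6) combined with inflated two-gene-class
frequency reproduces almost the same count distribution, and for a
repertoire of hundreds of low-frequency alleles per-slot sharing anywhere
near 0.5 is biologically impossible (it is homozygosity plus rare gene
conversion, bounded near Σfᵢ² ≈ 0.004 plus the conversion rate). The bound
selects the interpretable branch of the ridge; raising `s_max` restores
the unrestricted maximum if wanted. An identifiability guard profiles the
last class frequency and warns when its 1.92-log-unit support interval is
wider than 0.2 (e.g. a handful of counts supported only on {2,3,4}).

Goodness-of-fit is a Pearson chi-square of observed versus fitted counts.
The co-occurrence test is a 2×2 presence/absence chi-square across
QC-passed individuals, continuity correction off by default to match the
conventional reporting of such statistics; the margins are presence of
each allele across individuals, the natural reading when the original
construction is unstated. The robustness check recomputes the count
distribution on individuals above a read threshold (default 500) and
reports the total-variation distance to the full-data distribution.

## Problem sizes

Default experiment sizes — 200 individuals at study-scale depth for the
end-to-end check, 50 replicates at n = 902 for parameter recovery, 200/100
replicates for the co-occurrence/Phi null calibrations, 100 random
instances per oracle-equivalence check — were chosen so the whole suite
and the acceptance script each complete in about a minute on one CPU while
keeping Monte-Carlo standard errors well inside the asserted tolerances.

## Known limitations

- Chimera screening requires both parents to survive as contigs in the
  same individual; a chimera whose parent dropped below detection is only
  caught by population-level validation.
- The clustering consensus is maintained per column of the founder's
  coordinates; long indel structure (absent from the emulated chemistry)
  would degrade the projection.
- The copy-number model assumes Hardy–Weinberg pairing of haplotype
  classes and cannot distinguish >G_max-gene haplotypes from calling
  artefacts; `g_max` is an input, not an inference.
- Bayesian site-by-site selection inference and breakpoint detection are
  out of scope; `selection.export_for_external` writes codon alignments
  (sequential FASTA, relaxed PHYLIP) for external services.
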