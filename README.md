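# mhctyper

Amplicon genotyping and molecular-evolution analysis for duplicated MHC
gene families — built around the typing problem posed by the MHC class II B
genes of the Eurasian Coot (*Fulica atra*), where up to three gene copies
per haplotype, hundreds of segregating alleles and the impossibility of
assigning alleles to loci make genotypes *sets of alleles* rather than
pairs.

The package is for immunogeneticists and molecular ecologists typing a
multigene family from barcoded amplicon reads (454-style or any
substitution-dominated chemistry). It provides:

- **`mhctyper.simulate`** — a synthetic-data generator with full ground
  truth: coalescent allele pools of 277-nt amplicons (7 nt of intron 1 +
  the 270-nt exon 2), copy-number-variable haplotypes, dual 4–8-nt barcodes
  at pairwise distance ≥ 3, lognormal read depth (mean ≈ 284, range
  29–2741), per-base substitution error and single-crossover PCR chimeras.
- **`mhctyper.demux`** — barcode demultiplexing with primer-context
  validation and fixed-offset trimming.
- **`mhctyper.calling`** — per-individual greedy clustering (≤ 2%
  mismatch, ≤ 6-nt gaps), 75%-threshold consensus with ambiguity-driven
  splitting, chimera screening, population-wide allele validation (≥ 2
  individuals, ≥ 12 reads; provisional singletons), 100%-match genotyping
  and the < 25-read individual QC rule.
- **`mhctyper.popgen`** — segregating sites *S*, total mutations η,
  nucleotide diversity π, mean pairwise differences *k*, Tajima's *D*
  (global and in 24-nt/3-nt sliding windows), synonymous-allele collapsing
  and the allele frequency spectrum.
- **`mhctyper.selection`** — modified Nei–Gojobori *d*<sub>N</sub>/*d*<sub>S</sub>
  with Jukes–Cantor correction, a codon-bootstrap *Z*-test of positive
  selection on the peptide-binding-region (PBR) partition, and the Phi
  (pairwise homoplasy index) recombination test.
- **`mhctyper.copynumber`** — exact distribution of distinct alleles per
  diploid under haplotype gene-count classes ``p = (p1, …, pG)`` with
  sharing rate *s* (``a = g1 + g2 − X``, ``X ~ Binomial(min(g1,g2), s)``),
  a maximum-likelihood fit of ``(p, s)``, allele co-occurrence chi-square
  tests and a read-depth robustness check.

## The core statistics

For an alignment of *n* allele sequences, Tajima's statistic is

    D = (k − S/a1) / sqrt(e1·S + e2·S(S−1)),   a1 = Σ_{i<n} 1/i,

with the canonical coefficients in *n*; positive *D* indicates an excess of
intermediate-frequency variants (balancing selection). Synonymous and
nonsynonymous rates use the modified Nei–Gojobori counting: potential sites
weight the single transition at each codon position by ``2R`` against the
two transversions, observed differences are averaged over all
minimum-length mutational pathways, and proportions are corrected by
``d = −(3/4)·ln(1 − 4p/3)``. Positive selection is tested one-tailed with
``Z = (dN − dS)/sqrt(se²_dN + se²_dS)``, standard errors from 1000 codon
bootstraps. Haplotype gene-count class frequencies are estimated by
maximising the multinomial likelihood of the observed alleles-per-
individual distribution against the exact model above.

## Worked example

```python
from mhctyper import simulate as sim, copynumber as cn, popgen
from mhctyper.demux import demultiplex_run
from mhctyper.calling import call_genotypes

pool = sim.generate_allele_pool(n_alleles=120, seed=7)
freqs = cn.HaplotypeClassFreqs(p=(0.55, 0.43, 0.02), s=0.02)
birds = sim.sample_population(pool, freqs, n_individuals=60, seed=8)
scheme = sim.make_barcode_scheme([b.individual_id for b in birds], seed=9)
reads, truth = sim.simulate_reads(birds, pool, scheme, sim.ReadSimParams(seed=10))

bins = demultiplex_run(reads, scheme, sim.DEFAULT_FW_PRIMER, sim.DEFAULT_RV_PRIMER)
catalog, table, _ = call_genotypes(bins.assigned)

counts = {}
for ind, row in table.pass_rows():
    a = len({x for x, _ in row})
    counts[a] = counts.get(a, 0) + 1
fit = cn.fit_copy_number(cn.AlleleCountDistribution(counts), g_max=3)

exon = [e.sequence[7:] for e in catalog.accepted().values()]
st = popgen.alignment_stats(exon)
```

prints (via the obvious `print` calls):

```
simulated 19387 reads for 60 individuals
assigned 19386/19387 reads
catalog: 52 confirmed + 36 provisional alleles
alleles per individual: {2: 26, 3: 21, 4: 12, 5: 1}
haplotype class frequencies: (0.652, 0.296, 0.052) sharing 0.0
S=172 eta=237 pi=0.178 k=47.98 D=1.38
```

Reading: of 60 birds, 26 carried two distinct alleles, 21 three, and so
on; the maximum-likelihood explanation is a population where ~65% of
haplotypes carry a single gene copy, ~30% two and ~5% three. The
polymorphism summary (172 variable sites, π = 0.178) describes the
recovered allele alignment.

The same pipeline is available from the shell:

```
mhctyper simulate --n-individuals 60 --n-alleles 120 --seed 7 \
    --fastq run.fastq --truth truth.tsv --scheme scheme.tsv
mhctyper call --fastq run.fastq --scheme scheme.tsv \
    --catalog-fasta catalog.fasta --catalog-tsv catalog.tsv \
    --genotypes-tsv genotypes.tsv
mhctyper copynumber --genotypes-tsv genotypes.tsv --out-json fit.json
```

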