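# milletmarkers

Marker discovery and population-genetic analysis tools for finger millet
(*Eleusine coracana*), an allotetraploid (AABB) orphan cereal. The package
covers the full desk-side workflow used when developing SSR and SNP markers
from genotyping-by-sequencing (GBS) or genome-survey contigs:

1. **SSR mining** — find perfect di-, tri- and tetranucleotide
   microsatellites in assembled contigs, with deterministic maximal-run
   semantics and canonical motif classes.
2. **SNP filtering** — apply quality / bi-allelicity / depth filters and,
   crucially for an allotetraploid, remove *homeologous* SNPs: sites that
   look heterozygous within a single genotype because the two sub-genomes
   diverge, not because the individual carries two alleles.
3. **Diversity statistics** — allele frequencies, gene diversity, Botstein
   polymorphism information content (PIC), observed heterozygosity and
   missing-data QC, overall and per accession group.
4. **Population structure** — identity-by-state distances, UPGMA
   clustering, a Gibbs-sampler admixture model, and Evanno's ΔK for
   choosing the number of populations.
5. **Synthetic data** — ground-truthed generators (planted SSRs, planted
   homeologous/allelic variant sites, admixed genotype matrices) so every
   component can be validated against a known answer.

The intended audience is plant-genetics researchers and bioinformaticians
building marker panels for minor crops, where read depth is modest,
selfing is high, and polyploidy makes naive SNP calling unreliable.

## Key statistics

For a locus with allele frequencies *p₁ … p_k*, gene diversity (expected
heterozygosity) is

> *H* = 1 − Σᵢ pᵢ²

and the Botstein polymorphism information content is

> PIC = 1 − Σᵢ pᵢ² − Σᵢ Σ_{j>i} 2 pᵢ² pⱼ²

Reported values are rounded to two decimals, half away from zero
(`round_half_away`), matching the convention of published marker tables.

## Worked example: mining SSRs and scoring loci

```python
from milletmarkers import (AlleleSpectrum, find_ssrs, gene_diversity, pic,
                           round_half_away, summarize_ssrs)

seq = ("TTACG" + "AG" * 9 + "CCATG" + "TTG" * 6 + "GAAC"
       + "ATCT" * 5 + "GGTTACA")
for locus in find_ssrs("contig_1", seq):
    print(locus.contig_id, locus.start, locus.end, locus.motif,
          locus.canonical_class, locus.n_repeats, sep="\t")
```

```
contig_1	4	22	GA	AG/CT	9
contig_1	26	44	TGT	AAC/GTT	6
contig_1	50	70	ATCT	AGAT/ATCT	5
```

Note the maximal-run semantics: the first repeat is reported as `GA`
starting at position 4, because the `G` preceding the literal `AG`×9 block
extends the period-2 stretch one base to the left, and loci are anchored
at the left edge of the maximal run. Motifs are grouped into canonical
classes (the lexicographically smallest rotation of the motif or its
reverse complement), so `GA` counts toward `AG/CT`.

Scoring bi-allelic loci at a few major-allele frequencies (MAF):

```python
for maf in (0.50, 0.80, 0.89):
    spectrum = AlleleSpectrum(("A", "B"), (maf, round(1 - maf, 10)))
    print(f"MAF {maf:.2f}:  gene diversity "
          f"{round_half_away(gene_diversity(spectrum)):.2f},  "
          f"PIC {round_half_away(pic(spectrum)):.2f}")
```

```
MAF 0.50:  gene diversity 0.50,  PIC 0.38
MAF 0.80:  gene diversity 0.32,  PIC 0.27
MAF 0.89:  gene diversity 0.20,  PIC 0.18
```

## Worked example: homeolog subtraction and structure

```python
from milletmarkers import (HomeologSet, best_k, delta_k, filter_sites,
                           gibbs_admixture, homeolog_positions, lnpd,
                           simulate_allotetraploid_variants,
                           simulate_genotype_matrix, substitution_spectrum,
                           subtract_homeologs)

self_sets, combined, truths = simulate_allotetraploid_variants(
    500_000, n_genotypes=2, degraded_fraction=0.2, seed=7)
print("combined sites:", len(combined))
kept = filter_sites(combined)
print("pass quality/biallelic/depth filters:", len(kept))
homeologs = homeolog_positions(
    [HomeologSet(g, {s.key for s in sites}) for g, sites in self_sets.items()])
retained = subtract_homeologs(kept, homeologs)
print("after homeolog subtraction:", len(retained))
truth_allelic = {(t.contig_id, t.position) for t in truths
                 if t.kind == "allelic"}
print("matches planted allelic truth:",
      {s.key for s in retained} == truth_allelic)
print("substitution spectrum:",
      {k: round(v, 3) for k, v in substitution_spectrum(retained).items()})
```

```
combined sites: 1097
pass quality/biallelic/depth filters: 914
after homeolog subtraction: 154
matches planted allelic truth: True
substitution spectrum: {'CT/AG': 0.604, 'AC/GT': 0.136, 'AT': 0.175, 'CG': 0.084}
```

Homeolog subtraction removes any site whose (contig, position) appears
heterozygous in *any* single genotype's self-alignment, so the retained
sites are the genuine allelic variants — recovered here exactly, because
the synthetic generator records its planted truth.

Choosing the number of populations with Evanno's ΔK:

```python
matrix, truth = simulate_genotype_matrix(2, 20, 80, divergence=1.0,
                                         alpha=0.1, seed=3)
table = {k: [lnpd(gibbs_admixture(matrix, k, burnin=200, reps=800, alpha=0.1,
                                  seed=run)) for run in range(2)]
         for k in range(1, 5)}
evanno = delta_k(table)
print(evanno[["mean_lnpd", "delta_k"]].round(2))
print("best K:", best_k(evanno))
```

```
   mean_lnpd  delta_k
K                    
1   -4476.17      NaN
2    -985.05  1103.93
3   -1160.57     0.07
4   -1352.96      NaN
best K: 2
```

## Command line

A `milletmarkers` console script exposes each stage
(`simulate`, `mine-ssr`, `filter-snps`, `diversity`, `upgma`, `structure`)
plus `run-all`, which executes the whole pipeline from a flat
`key = value` config file and writes all artifacts (TSV tables, VCFs,
Newick tree, ΔK table, run log) to an output directory:

```bash
milletmarkers run-all --outdir out/demo --seed 42
milletmarkers mine-ssr contigs.fasta --out ssr_loci.tsv
```

## Bundled validation tables

`milletmarkers.datasets` ships two small per-locus marker-validation
tables (`ssr_validation()`, 49 SSR markers; `snp_validation()`, 80 SNP
markers with per-group PIC for wild and cultivated accessions), used by
the test suite to check that the statistics reproduce published
two-decimal values.

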