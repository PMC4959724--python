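# Methods

This note records the models, conventions and numerical choices behind
each component, including deliberate deviations from common defaults.

## SSR mining (`milletmarkers.ssr`)

A perfect SSR is a run of an exactly repeated 2–4 bp motif. Defaults:
minimum 5 repeat units and minimum 10 bp span (so dinucleotides need 5
units, trinucleotides 4×3=12 < 10 is moot — 5 units = 15 bp,
tetranucleotides 5 units = 20 bp; both constraints are enforced
independently so they remain meaningful if the caller relaxes one).

Conventions, chosen to make the miner deterministic and checkable against
an exhaustive oracle:

- **Maximal runs, left-anchored.** For each unit length *u*, a maximal
  periodic stretch is a maximal interval where `seq[x] == seq[x+u]`.
  The reported locus starts at the left edge of that stretch and spans
  the largest whole number of units (`floor(stretch / u) × u` bases).
  Partial trailing units are not counted toward the repeat number.
- **Runs never cross `N`**; ambiguous bases break periodicity.
- **Reducible motifs are excluded.** A motif whose period divides its
  length (e.g. `ATAT`, `AA`) is reported at its smallest period only.
- **Smallest-unit priority.** When runs of different unit lengths overlap,
  the locus with the smaller unit wins; ties cannot occur because equal
  units at the same position are the same run.
- **Canonical classes.** A motif's class is the lexicographically smaller
  of the minimal rotations of the motif and of its reverse complement,
  printed as `MOTIF/REVCOMP` (e.g. `GA` → `AG/CT`); self-complementary
  classes print once (`AT`).

Marker density is reported as "1 per X kb" (one decimal), switching to
Mb above 10 000 kb, and "undefined" for zero markers.

## Variant filtering (`milletmarkers.variants`)

Sites are retained when **all** hold, inclusively: quality ≥ 30, total
distinct alleles ≤ 2, depth ≥ 3. A missing depth fails the depth filter
(conservative: unknown evidence is not passing evidence).

**Homeologous SNP removal.** In an allotetraploid, aligning one
genotype's reads to its own contigs still yields heterozygous-looking
sites wherever the A and B sub-genomes diverge. Any site that is
heterozygous in a single-genotype self-alignment is therefore a homeolog
candidate. We take the union of homeolog positions across all genotypes
and remove those (contig, position) keys from the combined call set. The
union (rather than per-genotype subtraction) is deliberate: a site proven
homeologous in one genotype is structurally homeologous in all, and a
false negative homeolog is costlier than a lost allelic site.

Substitutions are summarized in four complementary-pair classes —
`CT/AG` (transitions), `AC/GT`, `AT`, `CG` (transversions) — since
strand is arbitrary in unanchored contigs.

## Diversity statistics (`milletmarkers.diversity`)

Allele frequencies count two alleles per non-missing diploid call.
Gene diversity is `1 − Σ pᵢ²`; Botstein PIC is
`1 − Σ pᵢ² − Σ_{i<j} 2 pᵢ² pⱼ²`. Values are rounded half away from zero
to two decimals (`round_half_away`), not banker's rounding, to match the
convention of published marker tables (0.375 → 0.38).

QC order matters and is fixed: first drop samples with **more than** 80%
missing calls, then drop loci with more than 90% missing or monomorphic
among the remaining samples. Thresholds are strict (`>`), so a sample at
exactly 80% missing is kept. Group-restricted PIC uses allele frequencies
within the group only and is reported as NA when the group is
monomorphic or has no calls.

## Population structure (`milletmarkers.popstruct`)

**IBS distance** between two samples is `1 − mean(shared/2)` over loci
where both are non-missing, `shared` being the number of alleles the two
unordered genotypes have in common (0, 1, 2).

**UPGMA** is implemented as the textbook average-linkage agglomeration:
merge the closest pair, set the new node's height to half the merge
distance, and update distances as size-weighted averages. Ties are broken
by lexicographic order of the cluster name sets, making the tree
deterministic. An optional outgroup only rotates (ladderizes) the tree;
it never changes topology or heights. Trees are `skbio.TreeNode` objects
and serialize to Newick.

**Admixture model.** A Gibbs sampler for the standard admixture model
with *independent* allele frequencies per population (the simpler of the
two classical prior choices; the correlated-frequencies model is out of
scope). Latent per-allele origins `z` are sampled from
`P(z=k) ∝ q_{ik} p_{kla}`, then `P ~ Dirichlet(1 + counts)` per
locus/population and `Q ~ Dirichlet(α + counts)` per sample. The sampler
is fully vectorized (Dirichlet draws via normalized gammas) and
seed-deterministic. Reported `Q` and `P` are posterior means over
post-burn-in sweeps. Default desk-scale run lengths (burn-in 200,
800 kept sweeps in the pipeline; 1000/5000 in the validation tests) are
package choices sized for laptop runtimes, not recommendations for
publication-grade inference.

**Model choice, `LnP(D)` and ΔK.** Each run's marginal-likelihood proxy
is `mean(trace) − var(trace, ddof=1)/2` over the stored post-burn-in
log-likelihood trace. Evanno's ΔK is `|L″(K)| / sd(L(K))` across
replicate runs, defined only for interior K with nonzero sd; `best_k`
takes the argmax. ΔK cannot select the boundary values of the tested
range — callers should bracket their candidate K.

**Run alignment.** Replicate runs suffer label switching. Alignment
minimizes the summed squared column differences against a reference run:
exhaustively over permutations for K ≤ 8, and by optimal linear-sum
assignment (Hungarian algorithm) above. Using an exact assignment rather
than a greedy heuristic means the two regimes provably agree where both
apply, which the tests check.

## Synthetic generators (`milletmarkers.synthetic`)

The generators exist to provide *exact* planted truth:

- `plant_ssrs` writes the requested loci into random background sequence
  and **rejection-resamples** any contig where mining would report
  anything other than the planted set (background repeats arise by
  chance), so mined == planted is guaranteed, not merely likely.
  Class mix defaults (unit 2 : 3 : 4 = 0.80 : 0.183 : 0.012) are treated
  as relative weights and normalized; loci counts are apportioned by
  largest remainder.
- `simulate_allotetraploid_variants` plants homeologous sites (binomial
  at rate 1/657 per bp) and allelic sites (rate 1/3306). Homeologs appear
  heterozygous in each carrier genotype's self-set and in the combined
  set; allelic sites appear only in the combined set as homozygous
  differences. Substitution classes are drawn with weights
  CT/AG 0.62, AC/GT 0.1525, AT 0.1525, CG 0.075. Quality ~ U(30, 60) and
  depth ~ 3 + Poisson(20), so all planted truths pass the default
  filters; an optional `degraded_fraction` adds *separate decoy* sites
  failing quality or depth. Decoys are kept distinct from truths so that
  noiseless recovery stays exact while the filters still have work to do.
- `simulate_genotype_matrix` draws population allele frequencies from a
  Balding–Nichols model with divergence parameter F (F = 1 gives fixed
  alternating frequencies — maximal differentiation), admixture rows
  from a block Dirichlet (own-population weight 1, others α), and
  genotypes by sampling two allele copies; a `selfing` probability
  forces homozygosity by duplicating a single draw. The planted `Q` and
  `P` are returned for validation.

What the generators do **not** emulate: read-level errors, mapping
artifacts, allele dropout, paralogy beyond the two sub-genomes, linkage
between loci, or realistic site-frequency spectra. They are validation
instruments, not population-genetic simulators.

## Pipeline and I/O

FASTA via Biopython, VCF via pysam (uncompressed VCF 4.2, `INFO/DP`,
`FORMAT/GT`; non-SNP records are skipped and counted; `./.` becomes a
missing call), genotype matrices as CSV with `A:B` calls and `NA`
missing. The pipeline config is a flat `key = value` file; unknown keys
are rejected and types are coerced from the dataclass defaults. Each
stage wraps failures in a `RuntimeError` naming the stage, and stages
fall back to conventional file names in the output directory so they can
be re-run standalone.

## Limitations

- Diploid genotype calls only; allele dosage in the tetraploid is not
  modeled (markers are scored disomically, as is standard for
  allotetraploids with strict bivalent pairing).
- The admixture sampler uses a fixed α and no correlated-frequencies
  prior; credible intervals are not reported.
- ΔK is undefined at the endpoints of the K range and is known to be
  biased toward K = 2 in weakly structured data.
- SSR mining targets perfect repeats only; compound and interrupted
  repeats are out of scope.
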