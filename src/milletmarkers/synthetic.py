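"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators emulate the statistical structure of the study system
(an inbred allotetraploid cereal) without simulating reads:

* contigs with planted perfect SSRs on a rejection-sampled background,
  so the truth list is exhaustive (mining recall and precision can be
  asserted exactly);
* per-genotype "self-mapped" variant sets containing homeologous sites
  (sub-genome divergence inside one genotype, seen as heterozygous
  calls) alongside a combined candidate set that mixes homeologous and
  truly allelic between-genotype SNPs;
* genotype matrices drawn from K ancestral populations with Dirichlet
  admixture, Balding-Nichols allele-frequency divergence and optional
  complete selfing.

Defaults follow the observed rates in finger millet: homeologous SNPs
at 1 per 657 bp, allelic SNPs at 1 per 3,300 bp, substitution classes
weighted 62% CT/AG and 7.5% CG (the remaining mass split evenly between
AC/GT and AT), and a planted SSR class mix of 80% di-, 18.3% tri- and
1.2% tetra-nucleotide motifs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .diversity import GenotypeMatrix
from .ssr import SSRParams, canonical_class, find_ssrs, _is_reducible
from .variants import VariantSite

__all__ = [
    "SSRTruth",
    "VariantTruth",
    "PopulationTruth",
    "plant_ssrs",
    "random_ssr_specs",
    "simulate_allotetraploid_variants",
    "simulate_genotype_matrix",
    "DEFAULT_SSR_CLASS_MIX",
    "DEFAULT_SPECTRUM_WEIGHTS",
    "HOMEOLOG_RATE",
    "ALLELIC_RATE",
]

#: Observed per-bp rate of homeologous SNPs (1 per 657 bp).
HOMEOLOG_RATE = 1.0 / 657.0
#: Observed per-bp rate of retained allelic SNPs (1 per ~3.3 kb).
ALLELIC_RATE = 1.0 / 3306.0
#: Planted SSR unit-size mix: di / tri / tetra.
DEFAULT_SSR_CLASS_MIX = {2: 0.80, 3: 0.183, 4: 0.012}
#: Substitution-class weights for simulated homeologous/allelic SNPs.
DEFAULT_SPECTRUM_WEIGHTS = {"CT/AG": 0.62, "AC/GT": 0.1525,
                            "AT": 0.1525, "CG": 0.075}

_CLASS_PAIRS = {
    "CT/AG": [("C", "T"), ("T", "C"), ("A", "G"), ("G", "A")],
    "AC/GT": [("A", "C"), ("C", "A"), ("G", "T"), ("T", "G")],
    "AT": [("A", "T"), ("T", "A")],
    "CG": [("C", "G"), ("G", "C")],
}
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SSRTruth:
    """A planted perfect repeat: motif repeated n_repeats times at start."""

    contig_id: str
    start: int  # 0-based
    motif: str
    n_repeats: int

    def __post_init__(self) -> None:
        if not (2 <= len(self.motif) <= 4):
            raise ValueError("motif unit must be 2-4 bp")
        if set(self.motif) - set("ACGT"):
            raise ValueError(f"motif must be over ACGT, got {self.motif!r}")
        if _is_reducible(self.motif):
            raise ValueError(f"motif {self.motif!r} reduces to a shorter unit")
        if self.n_repeats < 5:
            raise ValueError("planted repeats must have n_repeats >= 5")

    @property
    def end(self) -> int:
        return self.start + self.n_repeats * len(self.motif)

    @property
    def sequence(self) -> str:
        return self.motif * self.n_repeats


@dataclass(frozen=True)
class VariantTruth:
    """A planted SNP, either homeologous (within-genotype) or allelic."""

    contig_id: str
    position: int  # 1-based
    kind: str      # "homeologous" | "allelic"
    ref: str
    alt: str


@dataclass
class PopulationTruth:
    """Ground truth of a simulated admixed sample set."""

    K: int
    Q_true: np.ndarray   # (n_samples, K)
    P_true: np.ndarray   # (K, n_loci) frequency of the alternate allele
    selfing: float


def _random_background(rng: np.random.Generator, length: int,
                       base_composition: np.ndarray) -> np.ndarray:
    return rng.choice(_BASES, size=length, p=base_composition)


def plant_ssrs(n_contigs: int, contig_length: int,
               ssr_specs: list[SSRTruth] | None = None,
               base_composition: tuple[float, float, float, float] | None = None,
               seed: int = 0, params: SSRParams | None = None,
               max_attempts: int = 200,
               ) -> tuple[list[tuple[str, str]], list[SSRTruth]]:
    """Contigs with planted SSRs and no accidental qualifying runs.

    Background bases are i.i.d. at ``base_composition`` (default
    uniform); any contig whose mined loci differ from its planted truth
    (an accidental run, or a planted run extended by flanking chance
    bases) is rejected and redrawn, so the truth list is exact.  Contigs
    are named ``contig_1`` .. ``contig_n``.
    """
    params = params or SSRParams()
    specs = list(ssr_specs or [])
    comp = np.full(4, 0.25) if base_composition is None else np.asarray(
        base_composition, dtype=float)
    if comp.shape != (4,) or abs(comp.sum() - 1.0) > 1e-9 or (comp < 0).any():
        raise ValueError("base_composition must be 4 probabilities summing to 1")
    rng = np.random.default_rng(seed)
    names = [f"contig_{i + 1}" for i in range(n_contigs)]
    by_contig: dict[str, list[SSRTruth]] = {n: [] for n in names}
    for spec in specs:
        if spec.contig_id not in by_contig:
            raise ValueError(f"spec names unknown contig {spec.contig_id!r}")
        if spec.end > contig_length or spec.start < 0:
            raise ValueError(f"planted span {spec} does not fit in contig")
        for other in by_contig[spec.contig_id]:
            if spec.start < other.end and other.start < spec.end:
                raise ValueError(f"planted spans overlap: {spec} vs {other}")
        by_contig[spec.contig_id].append(spec)

    records: list[tuple[str, str]] = []
    for name in names:
        planted = sorted(by_contig[name], key=lambda s: s.start)
        expected = {(s.start, s.end, s.motif) for s in planted}
        for _ in range(max_attempts):
            seq = _random_background(rng, contig_length, comp)
            for s in planted:
                seq[s.start:s.end] = list(s.sequence)
            text = "".join(seq)
            mined = {(l.start, l.end, l.motif)
                     for l in find_ssrs(name, text, params)}
            if mined == expected:
                records.append((name, text))
                break
        else:
            raise RuntimeError(
                f"could not draw a clean background for {name} in "
                f"{max_attempts} attempts; lower the contig length or "
                "base-composition skew")
    truths = [s for n in names for s in sorted(by_contig[n], key=lambda t: t.start)]
    return records, truths


def random_ssr_specs(n_ssrs: int, n_contigs: int, contig_length: int,
                     class_mix: dict[int, float] | None = None,
                     repeat_range: tuple[int, int] = (5, 12),
                     seed: int = 0) -> list[SSRTruth]:
    """Random non-overlapping planting specs with an exact unit-size mix.

    Unit-size counts are apportioned by largest remainder so the mix of
    the returned list matches ``class_mix`` as closely as n_ssrs allows.
    """
    mix = dict(class_mix or DEFAULT_SSR_CLASS_MIX)
    total = sum(mix.values())
    if total <= 0 or any(v < 0 for v in mix.values()):
        raise ValueError("class_mix weights must be non-negative, sum > 0")
    mix = {u: v / total for u, v in mix.items()}  # relative weights
    rng = np.random.default_rng(seed)
    # largest-remainder apportionment
    raw = {u: n_ssrs * f for u, f in mix.items()}
    counts = {u: int(v) for u, v in raw.items()}
    short = n_ssrs - sum(counts.values())
    for u in sorted(raw, key=lambda u: raw[u] - counts[u], reverse=True)[:short]:
        counts[u] += 1

    occupied: dict[str, list[tuple[int, int]]] = {
        f"contig_{i + 1}": [] for i in range(n_contigs)}
    specs: list[SSRTruth] = []
    units = [u for u, c in counts.items() for _ in range(c)]
    rng.shuffle(units)
    for unit in units:
        for _ in range(1000):
            motif = "".join(rng.choice(_BASES, size=unit))
            if _is_reducible(motif):
                continue
            reps = int(rng.integers(repeat_range[0], repeat_range[1] + 1))
            span = unit * reps
            contig = f"contig_{int(rng.integers(n_contigs)) + 1}"
            # 1 bp guard band so planted runs cannot merge
            start = int(rng.integers(1, contig_length - span - 1))
            if all(start - 1 >= e or s >= start + span + 1
                   for s, e in occupied[contig]):
                occupied[contig].append((start, start + span))
                specs.append(SSRTruth(contig, start, motif, reps))
                break
        else:
            raise RuntimeError("could not place all SSR specs without overlap")
    return specs


def _draw_substitutions(rng: np.random.Generator, n: int,
                        weights: dict[str, float]) -> list[tuple[str, str]]:
    classes = list(weights)
    w = np.asarray([weights[c] for c in classes], dtype=float)
    w = w / w.sum()
    picks = rng.choice(len(classes), size=n, p=w)
    out = []
    for idx in picks:
        pairs = _CLASS_PAIRS[classes[idx]]
        out.append(pairs[int(rng.integers(len(pairs)))])
    return out


def simulate_allotetraploid_variants(
        contig_length: int, n_genotypes: int = 2,
        homeolog_rate: float = HOMEOLOG_RATE,
        allelic_rate: float = ALLELIC_RATE,
        spectrum_weights: dict[str, float] | None = None,
        degraded_fraction: float = 0.0,
        seed: int = 0, contig_id: str = "contig_1",
        ) -> tuple[dict[str, list[VariantSite]], list[VariantSite],
                   list[VariantTruth]]:
    """Per-genotype self variant sets plus a combined candidate set.

    Homeologous truths appear as heterozygous sites in the self set of
    one or more genotypes *and* in the combined candidate set; allelic
    truths appear only in the combined set, as homozygous differences
    between genotypes.  Each position carries at most one truth.  All
    truth sites pass the quality (>= 30) and depth (>= 3) screens; when
    ``degraded_fraction`` > 0, that fraction (relative to the truth
    count) of extra decoy sites failing one screen is mixed into the
    combined set.
    """
    if not (0 < homeolog_rate < 1) or not (0 < allelic_rate < 1):
        raise ValueError("rates must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    genotypes = [f"G{i + 1}" for i in range(n_genotypes)]
    weights = spectrum_weights or DEFAULT_SPECTRUM_WEIGHTS

    n_hom = rng.binomial(contig_length, homeolog_rate)
    n_all = rng.binomial(contig_length, allelic_rate)
    n_deg = int(round(degraded_fraction * (n_hom + n_all)))
    positions = rng.choice(contig_length, size=n_hom + n_all + n_deg,
                           replace=False) + 1  # 1-based, collision-free
    hom_pos = np.sort(positions[:n_hom])
    all_pos = np.sort(positions[n_hom:n_hom + n_all])
    deg_pos = np.sort(positions[n_hom + n_all:])

    def site(pos: int, ref: str, alt: str,
             calls: dict[str, tuple[int, int] | None],
             quality: float | None = None,
             depth: int | None = -1) -> VariantSite:
        q = float(rng.uniform(30.0, 60.0)) if quality is None else quality
        d = int(rng.poisson(20) + 3) if depth == -1 else depth
        return VariantSite(contig_id, int(pos), ref, [alt], q, d, dict(calls))

    truths: list[VariantTruth] = []
    self_sets: dict[str, list[VariantSite]] = {g: [] for g in genotypes}
    combined: list[VariantSite] = []

    for pos, (ref, alt) in zip(hom_pos, _draw_substitutions(rng, n_hom, weights)):
        truths.append(VariantTruth(contig_id, int(pos), "homeologous", ref, alt))
        carriers = [g for g in genotypes if rng.random() < 0.5]
        if not carriers:
            carriers = [genotypes[int(rng.integers(n_genotypes))]]
        for g in carriers:
            self_sets[g].append(site(pos, ref, alt, {g: (0, 1)}))
        combined.append(site(pos, ref, alt,
                             {g: (0, 1) if g in carriers else (0, 0)
                              for g in genotypes}))

    for pos, (ref, alt) in zip(all_pos, _draw_substitutions(rng, n_all, weights)):
        truths.append(VariantTruth(contig_id, int(pos), "allelic", ref, alt))
        gt = {g: (0, 0) for g in genotypes}
        alt_carriers = rng.permutation(n_genotypes)[
            :int(rng.integers(1, n_genotypes))] if n_genotypes > 1 else [0]
        for idx in np.atleast_1d(alt_carriers):
            gt[genotypes[int(idx)]] = (1, 1)
        combined.append(site(pos, ref, alt, gt))

    for pos, (ref, alt) in zip(deg_pos, _draw_substitutions(rng, n_deg, weights)):
        if rng.random() < 0.5:
            s = site(pos, ref, alt, {g: (0, 1) for g in genotypes},
                     quality=float(rng.uniform(0.0, 29.9)))
        else:
            s = site(pos, ref, alt, {g: (0, 1) for g in genotypes},
                     depth=int(rng.integers(0, 3)))
        combined.append(s)

    combined.sort(key=lambda s: s.position)
    truths.sort(key=lambda t: t.position)
    return self_sets, combined, truths


def simulate_genotype_matrix(K: int, n_per_pop: int, n_loci: int,
                             divergence: float = 0.3, alpha: float = 0.1,
                             selfing: float = 0.0, missing_rate: float = 0.0,
                             seed: int = 0,
                             ) -> tuple[GenotypeMatrix, PopulationTruth]:
    """Bi-allelic genotype matrix drawn from K admixed ancestral populations.

    Population allele frequencies follow a Balding-Nichols model around
    a uniform ancestral frequency with divergence parameter F in (0, 1);
    ``divergence`` = 1 fixes opposite alleles in alternating populations
    (maximal differentiation).  Sample i of block k draws its admixture
    row from Dirichlet with weight 1 on its own population and ``alpha``
    on the others, so small alpha gives nearly pure individuals.  With
    probability ``selfing`` a call is forced homozygous by duplicating a
    single drawn allele.
    """
    if K < 1 or n_loci < 1 or n_per_pop < 1:
        raise ValueError("K, n_per_pop and n_loci must be >= 1")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if not (0 <= selfing <= 1) or not (0 <= missing_rate <= 1):
        raise ValueError("selfing and missing_rate must lie in [0, 1]")
    if not (0 <= divergence <= 1):
        raise ValueError("divergence must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = K * n_per_pop

    if K == 1:
        P = rng.uniform(0.05, 0.95, size=(1, n_loci))
    elif divergence >= 1.0:
        P = np.tile((np.arange(K) % 2).astype(float)[:, None], (1, n_loci))
    elif divergence == 0.0:
        P = np.tile(rng.uniform(0.05, 0.95, size=n_loci)[None, :], (K, 1))
    else:
        anc = rng.uniform(0.05, 0.95, size=n_loci)
        f = (1.0 - divergence) / divergence
        P = rng.beta(anc * f, (1.0 - anc) * f, size=(K, n_loci))

    Q = np.zeros((n, K))
    for k in range(K):
        conc = np.full(K, alpha)
        conc[k] = 1.0
        Q[k * n_per_pop:(k + 1) * n_per_pop] = rng.dirichlet(conc, size=n_per_pop)
    if K == 1:
        Q[:] = 1.0

    sample_ids = [f"pop{k + 1}_s{i + 1}" for k in range(K)
                  for i in range(n_per_pop)]
    groups = {sid: f"pop{k + 1}" for k in range(K)
              for sid in sample_ids[k * n_per_pop:(k + 1) * n_per_pop]}
    locus_ids = [f"L{j + 1}" for j in range(n_loci)]

    calls: list[list[tuple[str, str] | None]] = []
    for i in range(n):
        row: list[tuple[str, str] | None] = []
        for j in range(n_loci):
            if rng.random() < missing_rate:
                row.append(None)
                continue
            if rng.random() < selfing:
                z = rng.choice(K, p=Q[i])
                a = "B" if rng.random() < P[z, j] else "A"
                row.append((a, a))
            else:
                pair = []
                for _ in range(2):
                    z = rng.choice(K, p=Q[i])
                    pair.append("B" if rng.random() < P[z, j] else "A")
                row.append(tuple(sorted(pair)))
        calls.append(row)

    matrix = GenotypeMatrix(sample_ids=sample_ids, locus_ids=locus_ids,
                            calls=calls, groups=groups)
    return matrix, PopulationTruth(K=K, Q_true=Q, P_true=P, selfing=selfing)
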