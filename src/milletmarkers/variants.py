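"""SNP filtering for an allotetraploid and substitution statistics.

Finger millet carries AA and BB sub-genomes; divergence between them
produces *homeologous* SNPs — heterozygous-looking sites inside a single
inbred genotype — that are not allelic variation between accessions.
These are identified per genotype by mapping each genotype back to the
common reference ("self sets") and eliminated from the combined
candidate set by position.  Candidates are additionally screened on
quality (>= 30), total allele count (<= 2) and site depth (>= 3), with
inclusive thresholds.

Substitution statistics group complementary strand-pairs: the four
classes are CT/AG (all transitions), AC/GT, AT and CG.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .ssr import format_frequency

__all__ = [
    "VariantSite",
    "HomeologSet",
    "VariantSummary",
    "classify_substitution",
    "filter_sites",
    "homeolog_positions",
    "subtract_homeologs",
    "substitution_spectrum",
    "variant_frequency",
    "summarize_variants",
    "SPECTRUM_CLASSES",
]

_BASES = set("ACGT")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Complementary-pair substitution classes; CT/AG covers both transitions.
SPECTRUM_CLASSES = ("CT/AG", "AC/GT", "AT", "CG")


@dataclass
class VariantSite:
    """One candidate variant with site-level quality/depth and genotype calls.

    ``depth`` is the site-level read depth; ``None`` means the caller did
    not report it (such sites fail a minimum-depth filter).  ``calls``
    maps sample id to a pair of allele indices (0 = ref) or ``None`` for
    a missing call.
    """

    contig_id: str
    position: int  # 1-based
    ref: str
    alts: list[str]
    quality: float
    depth: int | None = None
    calls: dict[str, tuple[int, int] | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position is 1-based and must be >= 1")
        if not self.alts:
            raise ValueError("alts must be non-empty")
        if self.ref in self.alts:
            raise ValueError("ref allele listed among alts")

    @property
    def n_alleles(self) -> int:
        return 1 + len(self.alts)

    @property
    def key(self) -> tuple[str, int]:
        return (self.contig_id, self.position)

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)


@dataclass
class HomeologSet:
    """Positions flagged as homeologous from one genotype's self-mapping."""

    genotype_id: str
    positions: set[tuple[str, int]]


@dataclass
class VariantSummary:
    n_transitions: int
    n_transversions: int
    tstv: float
    spectrum: dict[str, float]
    frequency: str


def classify_substitution(ref: str, alt: str) -> str:
    """'transition' for A<->G and C<->T, 'transversion' otherwise."""
    if ref not in _BASES or alt not in _BASES:
        raise ValueError(f"bases must be in ACGT, got {ref!r}/{alt!r}")
    if ref == alt:
        raise ValueError("ref and alt are identical: not a substitution")
    return "transition" if {ref, alt} in ({"A", "G"}, {"C", "T"}) else "transversion"


def substitution_class(ref: str, alt: str) -> str:
    """Complementary-pair class of a bi-allelic substitution.

    The unordered base pair and its complement collapse to one label,
    e.g. C->T, T->C, A->G and G->A all fall in ``CT/AG``.
    """
    if classify_substitution(ref, alt) == "transition":
        return "CT/AG"
    pair = frozenset((ref, alt))
    if pair == frozenset("AT"):
        return "AT"
    if pair == frozenset("CG"):
        return "CG"
    return "AC/GT"


def filter_sites(sites: list[VariantSite], min_quality: float = 30.0,
                 max_alleles: int = 2, min_depth: int = 3) -> list[VariantSite]:
    """Quality/allele-count/depth screen with inclusive thresholds.

    A site whose depth is unreported fails the depth criterion.
    Order is preserved; the input list is not modified.
    """
    return [
        s for s in sites
        if s.quality >= min_quality
        and s.n_alleles <= max_alleles
        and s.depth is not None and s.depth >= min_depth
    ]


def homeolog_positions(self_sets: list[HomeologSet]) -> set[tuple[str, int]]:
    """Union of homeologous positions over all genotypes' self sets."""
    out: set[tuple[str, int]] = set()
    for hs in self_sets:
        out |= hs.positions
    return out


def subtract_homeologs(candidates: list[VariantSite],
                       homeologs: set[tuple[str, int]]) -> list[VariantSite]:
    """Drop candidates whose (contig, position) is a known homeolog."""
    return [s for s in candidates if s.key not in homeologs]


def substitution_spectrum(sites: list[VariantSite]) -> dict[str, float]:
    """Fraction of bi-allelic sites in each complementary-pair class."""
    for s in sites:
        if len(s.alts) != 1:
            raise ValueError(f"multi-allelic site at {s.key}; spectrum is "
                             "defined for bi-allelic SNPs only")
    counts = Counter(substitution_class(s.ref, s.alts[0]) for s in sites)
    total = sum(counts.values())
    return {cls: counts[cls] / total for cls in SPECTRUM_CLASSES if counts[cls]}


def variant_frequency(count: int, total_bp: int) -> str:
    """Marker density as ``1 per X kb``; undefined when count is zero."""
    if total_bp <= 0:
        raise ValueError("total_bp must be positive")
    return format_frequency(total_bp, count)


def summarize_variants(sites: list[VariantSite], total_bp: int) -> VariantSummary:
    """Ts/Tv ratio, substitution spectrum and per-bp frequency of a SNP set."""
    kinds = Counter(classify_substitution(s.ref, s.alts[0]) for s in sites)
    ts, tv = kinds["transition"], kinds["transversion"]
    return VariantSummary(
        n_transitions=ts,
        n_transversions=tv,
        tstv=ts / tv if tv else float("inf"),
        spectrum=substitution_spectrum(sites) if sites else {},
        frequency=variant_frequency(len(sites), total_bp) if sites else "undefined",
    )
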