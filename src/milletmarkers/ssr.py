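"""Perfect microsatellite (SSR) mining.

Finds maximal perfect tandem repeats of di-, tri- and tetra-nucleotide
motifs in assembled contigs, classifies motifs into strand/rotation
canonical classes, and summarises class counts and genomic frequencies
("1 per X kb").

Conventions
-----------
* Coordinates are 0-based half-open internally; reports render 1-based.
* A run must be *maximal*: it cannot be extended by one motif unit on
  either side.  A partial trailing unit does not count toward the
  repeat number.
* Motifs that are whole repetitions of a shorter unit (``AA``,
  ``ATAT``) are never reported at the larger unit size; mononucleotide
  runs are excluded entirely.
* Where runs of different unit sizes overlap, the smallest unit wins.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

__all__ = [
    "SSRParams",
    "SSRLocus",
    "SSRSummary",
    "canonical_class",
    "find_ssrs",
    "summarize_ssrs",
    "format_frequency",
]

_DNA = set("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class SSRParams:
    """Mining thresholds: unit sizes 2-4, at least 5 repeats, span >= 10 bp."""

    min_unit: int = 2
    max_unit: int = 4
    min_repeats: int = 5
    min_length: int = 10

    def __post_init__(self) -> None:
        if not (2 <= self.min_unit <= self.max_unit <= 4):
            raise ValueError("unit sizes must satisfy 2 <= min_unit <= max_unit <= 4")
        if self.min_repeats < 2:
            raise ValueError("min_repeats must be >= 2")
        if self.min_length < self.min_unit * 2:
            raise ValueError("min_length must be >= 2 motif units")


@dataclass(frozen=True)
class SSRLocus:
    """One perfect tandem repeat: [start, end) span of n_repeats x motif."""

    contig_id: str
    start: int
    end: int
    motif: str
    canonical_class: str
    n_repeats: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def unit(self) -> int:
        return len(self.motif)


@dataclass
class SSRSummary:
    """Counts by unit size and canonical class plus per-class genomic frequency."""

    total: int
    total_bp: int
    by_unit: dict[int, int]
    by_class: dict[str, int]
    frequency: dict[str, str] = field(default_factory=dict)


def _is_reducible(motif: str) -> bool:
    """True if motif is a whole-number repetition of a shorter unit."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return True
    return False


def _rotation_min(motif: str) -> str:
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def canonical_class(motif: str) -> str:
    """Canonical strand-pair label of a motif.

    All rotations of a motif and of its reverse complement share one
    label: the two rotation-minima rendered smaller-first, e.g. ``GA``,
    ``AG``, ``CT`` and ``TC`` all map to ``AG/CT``.  When both strands
    give the same rotation-minimum (``AT``) the label is that single
    string.
    """
    if not (2 <= len(motif) <= 4):
        raise ValueError(f"motif length must be 2-4, got {motif!r}")
    if set(motif) - _DNA:
        raise ValueError(f"motif must be over ACGT, got {motif!r}")
    if _is_reducible(motif):
        raise ValueError(f"motif {motif!r} reduces to a shorter unit")
    fwd = _rotation_min(motif)
    rev = _rotation_min(motif.translate(_COMPLEMENT)[::-1])
    if fwd == rev:
        return fwd
    a, b = sorted((fwd, rev))
    return f"{a}/{b}"


def _runs_at_unit(seq: str, unit: int, min_repeats: int, min_length: int,
                  contig_id: str) -> list[SSRLocus]:
    """Maximal perfect runs of one unit size (reducible motifs skipped).

    A run starts at the left edge of a maximal periodic stretch (the
    preceding base breaks the period, so the run cannot slide left) and
    counts only whole motif units; a partial trailing unit is dropped.
    """
    n = len(seq)
    out: list[SSRLocus] = []
    x = 0
    while x < n - unit:
        if seq[x] != "N" and seq[x] == seq[x + unit]:
            a = x
            while x < n - unit and seq[x] != "N" and seq[x] == seq[x + unit]:
                x += 1
            reps = ((x - a) + unit) // unit
            motif = seq[a:a + unit]
            if (reps >= min_repeats and reps * unit >= min_length
                    and not _is_reducible(motif)):
                out.append(SSRLocus(contig_id, a, a + reps * unit, motif,
                                    canonical_class(motif), reps))
        else:
            x += 1
    return out


def find_ssrs(contig_id: str, seq: str, params: SSRParams | None = None) -> list[SSRLocus]:
    """All maximal perfect SSRs in one sequence under the mining thresholds.

    Overlapping candidate runs of different unit sizes are resolved in
    favour of the smaller unit.  Runs never extend across ``N``.
    """
    params = params or SSRParams()
    seq = seq.upper()
    if set(seq) - (_DNA | {"N"}):
        bad = sorted(set(seq) - (_DNA | {"N"}))
        raise ValueError(f"non-DNA characters in sequence: {bad}")
    accepted: list[SSRLocus] = []
    covered: list[tuple[int, int]] = []
    for unit in range(params.min_unit, params.max_unit + 1):
        for locus in _runs_at_unit(seq, unit, params.min_repeats,
                                   params.min_length, contig_id):
            if any(locus.start < e and s < locus.end for s, e in covered):
                continue
            accepted.append(locus)
        covered = [(l.start, l.end) for l in accepted]
    accepted.sort(key=lambda l: (l.start, l.unit))
    return accepted


def format_frequency(total_bp: int, count: int) -> str:
    """Render marker density as ``1 per X kb`` (or Mb above 1,000 kb)."""
    if count == 0:
        return "undefined"
    bp_per = total_bp / count
    kb = bp_per / 1_000
    if kb >= 1_000:
        return f"1 per {kb / 1_000:.1f} Mb"
    return f"1 per {kb:.1f} kb"


def summarize_ssrs(loci: list[SSRLocus], total_bp: int) -> SSRSummary:
    """Per-unit-size and per-class counts with genomic frequencies."""
    if total_bp <= 0:
        raise ValueError("total_bp must be positive")
    by_unit = Counter(l.unit for l in loci)
    by_class = Counter(l.canonical_class for l in loci)
    summary = SSRSummary(total=len(loci), total_bp=total_bp,
                         by_unit=dict(sorted(by_unit.items())),
                         by_class=dict(sorted(by_class.items())))
    summary.frequency["ALL"] = format_frequency(total_bp, summary.total)
    for unit, cnt in summary.by_unit.items():
        summary.frequency[f"unit{unit}"] = format_frequency(total_bp, cnt)
    for cls, cnt in summary.by_class.items():
        summary.frequency[cls] = format_frequency(total_bp, cnt)
    return summary
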