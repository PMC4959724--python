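"""Per-locus marker diversity statistics and QC for genotype matrices.

Implements the marker-validation summaries used for KASPar-style
bi-allelic calls across wild and cultivated accessions: major allele
frequency, allele number, gene diversity (expected heterozygosity),
observed heterozygosity and Botstein's polymorphism information content

    PIC = 1 - sum_i p_i^2 - sum_{i<j} 2 p_i^2 p_j^2,

plus the QC exclusions applied before reporting: samples with more than
80% missing calls are dropped first, then loci with more than 90%
missing calls or that are monomorphic across the retained samples.
Group PIC (e.g. wild vs cultivated) uses group-restricted allele
frequencies and is reported as not-applicable for a locus monomorphic
within that group.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "AlleleSpectrum",
    "allele_frequencies",
    "pic",
    "gene_diversity",
    "observed_heterozygosity",
    "qc_filter",
    "locus_summary",
    "polymorphic_count",
    "round_half_away",
]

MISSING = "NA"


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (0.375 -> 0.38), unlike banker's rounding."""
    factor = 10 ** ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass
class GenotypeMatrix:
    """Samples x loci matrix of unordered diploid allele-pair calls.

    ``calls[i][j]`` is a tuple of two allele strings or ``None`` for a
    missing call.  ``groups`` maps sample id to a population label
    (e.g. ``wild`` / ``cultivated``); unlisted samples are unassigned.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    calls: list[list[tuple[str, str] | None]]
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.calls) != len(self.sample_ids):
            raise ValueError("calls row count != number of samples")
        for row in self.calls:
            if len(row) != len(self.locus_ids):
                raise ValueError("calls column count != number of loci")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def locus_calls(self, j: int) -> list[tuple[str, str] | None]:
        return [row[j] for row in self.calls]

    def sample_missing_fraction(self, i: int) -> float:
        row = self.calls[i]
        return sum(c is None for c in row) / len(row)

    def locus_missing_fraction(self, j: int) -> float:
        col = self.locus_calls(j)
        return sum(c is None for c in col) / len(col)

    def subset(self, samples: list[int] | None = None,
               loci: list[int] | None = None) -> "GenotypeMatrix":
        si = list(range(self.n_samples)) if samples is None else samples
        lj = list(range(self.n_loci)) if loci is None else loci
        ids = [self.sample_ids[i] for i in si]
        return GenotypeMatrix(
            sample_ids=ids,
            locus_ids=[self.locus_ids[j] for j in lj],
            calls=[[self.calls[i][j] for j in lj] for i in si],
            groups={s: g for s, g in self.groups.items() if s in set(ids)},
        )

    def to_frame(self) -> pd.DataFrame:
        """Render as a DataFrame of ``A:B`` strings with ``NA`` for missing."""
        data = [[MISSING if c is None else f"{c[0]}:{c[1]}" for c in row]
                for row in self.calls]
        return pd.DataFrame(data, index=self.sample_ids, columns=self.locus_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame,
                   groups: dict[str, str] | None = None) -> "GenotypeMatrix":
        calls: list[list[tuple[str, str] | None]] = []
        for _, row in frame.iterrows():
            parsed: list[tuple[str, str] | None] = []
            for v in row:
                if pd.isna(v) or v == MISSING:
                    parsed.append(None)
                else:
                    a, b = str(v).split(":")
                    parsed.append((a, b))
            calls.append(parsed)
        return cls(sample_ids=[str(s) for s in frame.index],
                   locus_ids=[str(c) for c in frame.columns],
                   calls=calls, groups=dict(groups or {}))


@dataclass(frozen=True)
class AlleleSpectrum:
    """Allele frequencies p_1..p_k at one locus (sum to 1)."""

    alleles: tuple[str, ...]
    p: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.alleles) != len(self.p) or not self.p:
            raise ValueError("alleles and frequencies must align and be non-empty")
        if any(f < 0 for f in self.p) or abs(sum(self.p) - 1.0) > 1e-9:
            raise ValueError("frequencies must be >= 0 and sum to 1")

    @property
    def k(self) -> int:
        return len(self.p)


def allele_frequencies(calls: list[tuple[str, str] | None]) -> AlleleSpectrum:
    """Allele frequencies by direct genotype counting (2 per non-missing call)."""
    counts: Counter[str] = Counter()
    for c in calls:
        if c is not None:
            counts[c[0]] += 1
            counts[c[1]] += 1
    if not counts:
        raise ValueError("all calls missing: allele frequencies undefined")
    total = sum(counts.values())
    alleles = tuple(sorted(counts))
    return AlleleSpectrum(alleles, tuple(counts[a] / total for a in alleles))


def gene_diversity(spectrum: AlleleSpectrum) -> float:
    """Expected heterozygosity 1 - sum p_i^2."""
    return 1.0 - sum(f * f for f in spectrum.p)


def pic(spectrum: AlleleSpectrum) -> float:
    """Botstein polymorphism information content.

    1 - sum_i p_i^2 - sum over ordered pairs i<j of 2 p_i^2 p_j^2; equals
    gene diversity minus the chance that two random informative matings
    are indistinguishable, hence PIC <= gene diversity.
    """
    p = spectrum.p
    het = sum(f * f for f in p)
    pair = sum(2.0 * p[i] ** 2 * p[j] ** 2
               for i in range(len(p)) for j in range(i + 1, len(p)))
    return 1.0 - het - pair


def observed_heterozygosity(calls: list[tuple[str, str] | None]) -> float:
    """Fraction of non-missing calls whose two alleles differ."""
    present = [c for c in calls if c is not None]
    if not present:
        raise ValueError("all calls missing: heterozygosity undefined")
    return sum(a != b for a, b in present) / len(present)


def _is_monomorphic(calls: list[tuple[str, str] | None]) -> bool:
    seen: set[str] = set()
    for c in calls:
        if c is not None:
            seen.update(c)
    return len(seen) <= 1


def qc_filter(matrix: GenotypeMatrix, max_sample_missing: float = 0.80,
              max_locus_missing: float = 0.90, drop_monomorphic: bool = True,
              ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Exclude failing samples, then failing or monomorphic loci.

    Samples with missing fraction strictly above ``max_sample_missing``
    are dropped first; then loci with missing fraction strictly above
    ``max_locus_missing`` or (optionally) monomorphic across the
    retained samples.  Returns the filtered matrix and an exclusion
    report (kind, id, reason).
    """
    exclusions: list[dict[str, str]] = []
    keep_samples = []
    for i in range(matrix.n_samples):
        frac = matrix.sample_missing_fraction(i)
        if frac > max_sample_missing:
            exclusions.append({"kind": "sample", "id": matrix.sample_ids[i],
                               "reason": f"missing fraction {frac:.3f} > "
                                         f"{max_sample_missing:.2f}"})
        else:
            keep_samples.append(i)
    trimmed = matrix.subset(samples=keep_samples)

    keep_loci = []
    for j in range(trimmed.n_loci):
        frac = trimmed.locus_missing_fraction(j)
        if frac > max_locus_missing:
            exclusions.append({"kind": "locus", "id": trimmed.locus_ids[j],
                               "reason": f"missing fraction {frac:.3f} > "
                                         f"{max_locus_missing:.2f}"})
        elif drop_monomorphic and _is_monomorphic(trimmed.locus_calls(j)):
            exclusions.append({"kind": "locus", "id": trimmed.locus_ids[j],
                               "reason": "monomorphic across retained samples"})
        else:
            keep_loci.append(j)
    result = trimmed.subset(loci=keep_loci)
    if result.n_samples == 0 or result.n_loci == 0:
        raise ValueError(
            f"QC removed everything ({len(exclusions)} exclusions); "
            "check missing-data thresholds and input matrix")
    return result, pd.DataFrame(exclusions, columns=["kind", "id", "reason"])


def locus_summary(matrix: GenotypeMatrix,
                  group_labels: tuple[str, ...] = ("wild", "cultivated"),
                  ) -> pd.DataFrame:
    """Per-locus MAF, allele number, gene diversity, Ho, PIC and group PIC.

    Group PIC columns hold NaN where the locus is monomorphic within the
    group (or the group has no callable data).  A footer row ``Mean``
    carries column means over the defined entries.
    """
    rows = []
    group_members = {
        g: [i for i, s in enumerate(matrix.sample_ids)
            if matrix.groups.get(s) == g]
        for g in group_labels
    }
    for j, locus in enumerate(matrix.locus_ids):
        calls = matrix.locus_calls(j)
        spec = allele_frequencies(calls)
        row = {
            "locus": locus,
            "maf": max(spec.p),
            "allele_number": spec.k,
            "gene_diversity": gene_diversity(spec),
            "heterozygosity": observed_heterozygosity(calls),
            "pic": pic(spec),
        }
        for g, members in group_members.items():
            gcalls = [calls[i] for i in members]
            col = f"pic_{g}"
            if not any(c is not None for c in gcalls) or _is_monomorphic(gcalls):
                row[col] = np.nan
            else:
                row[col] = pic(allele_frequencies(gcalls))
        rows.append(row)
    table = pd.DataFrame(rows).set_index("locus")
    table.loc["Mean"] = table.mean()
    return table


def polymorphic_count(summary: pd.DataFrame, group: str) -> int:
    """Number of loci with a defined (non-NaN) PIC within the group."""
    col = f"pic_{group}"
    if col not in summary.columns:
        raise KeyError(f"unknown group {group!r}; summary has no column {col}")
    body = summary.drop(index="Mean", errors="ignore")
    return int(body[col].notna().sum())
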