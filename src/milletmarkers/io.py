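"""Readers and writers for the formats the pipeline consumes.

FASTA through Biopython, VCF 4.2 through pysam, genotype/group tables
through pandas.  Coordinates are 1-based in VCF and converted to/from
the package's internal conventions here, nowhere else.  Round trips are
lossless for every field the pipeline uses.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .diversity import GenotypeMatrix
from .variants import VariantSite

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_vcf",
    "write_vcf",
    "read_genotype_csv",
    "write_genotype_csv",
    "read_groups_csv",
    "write_groups_csv",
]

logger = logging.getLogger("milletmarkers")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Ordered (id, sequence) records, upper-cased; duplicate ids rejected."""
    records = [(rec.id, str(rec.seq).upper())
               for rec in SeqIO.parse(str(path), "fasta")]
    ids = [r[0] for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate FASTA ids: {dupes}")
    if not records:
        logger.warning("FASTA file %s contains no records", path)
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    SeqIO.write((SeqRecord(Seq(seq), id=name, description="")
                 for name, seq in records), str(path), "fasta")


def _vcf_header(sites: list[VariantSite],
                sample_ids: list[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line("##source=milletmarkers")
    header.add_line('##INFO=<ID=DP,Number=1,Type=Integer,'
                    'Description="Site read depth">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    contigs: dict[str, int] = {}
    for s in sites:
        contigs[s.contig_id] = max(contigs.get(s.contig_id, 0), s.position)
    for name, max_pos in contigs.items():
        header.contigs.add(name, length=max_pos + 1)
    for sid in sample_ids:
        header.add_sample(sid)
    return header


def write_vcf(sites: list[VariantSite], path: str | Path) -> None:
    """Write sites as uncompressed VCF 4.2 with GT calls and site DP."""
    sample_ids = sorted({sid for s in sites for sid in s.calls})
    header = _vcf_header(sites, sample_ids)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for s in sorted(sites, key=lambda s: (s.contig_id, s.position)):
            rec = out.new_record(contig=s.contig_id, start=s.position - 1,
                                 alleles=(s.ref, *s.alts), qual=s.quality)
            if s.depth is not None:
                rec.info["DP"] = s.depth
            for sid in sample_ids:
                call = s.calls.get(sid)
                rec.samples[sid]["GT"] = call if call is not None else (None, None)
            out.write(rec)


def read_vcf(path: str | Path) -> tuple[list[VariantSite], int]:
    """Parse SNP records; indels/MNPs are skipped and counted.

    Returns (sites, number of skipped non-SNP records).  Site depth
    comes from INFO/DP and is ``None`` when absent.  Missing genotypes
    (``./.``) become ``None`` calls.
    """
    sites: list[VariantSite] = []
    skipped = 0
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise ValueError(f"malformed VCF {path}: {exc}") from exc
    with vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            alts = list(rec.alts or [])
            if not alts or len(rec.ref) != 1 or any(len(a) != 1 for a in alts):
                skipped += 1
                continue
            calls: dict[str, tuple[int, int] | None] = {}
            for sid in samples:
                gt = rec.samples[sid].get("GT")
                if gt is None or any(a is None for a in gt):
                    calls[sid] = None
                else:
                    calls[sid] = (int(gt[0]), int(gt[1]))
            depth = rec.info.get("DP")
            sites.append(VariantSite(
                contig_id=rec.contig, position=rec.pos, ref=rec.ref,
                alts=alts,
                quality=float(rec.qual) if rec.qual is not None else 0.0,
                depth=int(depth) if depth is not None else None,
                calls=calls))
    if skipped:
        logger.info("skipped %d non-SNP records in %s", skipped, path)
    return sites, skipped


def write_genotype_csv(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Samples x loci CSV of ``A:B`` calls with ``NA`` for missing."""
    matrix.to_frame().to_csv(path, index_label="sample")


def read_genotype_csv(path: str | Path,
                      groups: dict[str, str] | None = None) -> GenotypeMatrix:
    frame = pd.read_csv(path, index_col="sample", dtype=str)
    return GenotypeMatrix.from_frame(frame, groups=groups)


def write_groups_csv(groups: dict[str, str], path: str | Path) -> None:
    pd.Series(groups, name="group").rename_axis("sample").to_csv(path)


def read_groups_csv(path: str | Path) -> dict[str, str]:
    frame = pd.read_csv(path, index_col="sample", dtype=str)
    return frame["group"].to_dict()
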