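"""VCF ingestion and tabular output — the pipeline's only contact with disk.

Input is one single- (or multi-) sample VCFv4.x per replicate with GT, AD,
DP and GQ FORMAT fields.  AD is authoritative for ref/alt counts; any DP
excess over sum(AD) (uninformative reads) is stored as ``other_count`` so
the targeted-stage noise filter can see it.  Records that cannot be used
are skipped and counted, never silently dropped and never fatal.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pysam

from .core import BASES, Genotype, GenotypeCall, Locus, ReadSupport

__all__ = [
    "SampleCallSet",
    "UnknownSampleError",
    "read_sample_calls",
    "write_vcf",
    "write_candidates",
    "read_candidate_loci",
    "CANDIDATE_COLUMNS",
]


class UnknownSampleError(KeyError):
    """Requested sample not present in the VCF."""


@dataclass
class SampleCallSet:
    """All genotype calls for one replicate of one sample."""

    sample_id: str
    replicate_id: str
    calls: dict[Locus, GenotypeCall]
    contig_lengths: dict[str, int] = field(default_factory=dict)
    #: ingestion tallies: total / retained / skipped_* counters
    counters: dict[str, int] = field(default_factory=dict)


_GT_FROM_ALLELES = {
    (0, 0): Genotype.HOM_REF,
    (0, 1): Genotype.HET,
    (1, 1): Genotype.HOM_ALT,
}

_GT_TO_STRING = {
    Genotype.HOM_REF: "0/0",
    Genotype.HET: "0/1",
    Genotype.HOM_ALT: "1/1",
    Genotype.MISSING: "./.",
}


def read_sample_calls(
    path: str | Path,
    sample: str | None = None,
    *,
    biallelic_only: bool = True,
    replicate_id: str | None = None,
) -> SampleCallSet:
    """Read per-locus genotype calls for one sample from a VCF.

    Parameters
    ----------
    path:
        VCF file (plain or bgzipped) with GT/AD/DP/GQ FORMAT fields.
    sample:
        Sample name; may be omitted for single-sample VCFs.
    biallelic_only:
        Skip (and count) records that are not biallelic SNVs.
    replicate_id:
        Label stored on the returned call set; defaults to the file stem.
    """
    path = Path(path)
    counters = {
        "total_records": 0,
        "retained": 0,
        "skipped_multiallelic": 0,
        "skipped_non_snv": 0,
        "skipped_missing_fields": 0,
        "skipped_duplicate_locus": 0,
    }
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if sample is None:
            if len(samples) != 1:
                raise UnknownSampleError(
                    f"{path}: sample name required for multi-sample VCF "
                    f"(found {samples})"
                )
            sample = samples[0]
        elif sample not in samples:
            raise UnknownSampleError(f"{path}: sample {sample!r} not in {samples}")

        contig_lengths = {
            name: contig.length
            for name, contig in vcf.header.contigs.items()
            if contig.length is not None
        }

        calls: dict[Locus, GenotypeCall] = {}
        for record in vcf:
            counters["total_records"] += 1
            alts = record.alts
            if alts is None or len(alts) == 0:
                if biallelic_only:
                    counters["skipped_non_snv"] += 1
                    continue
            if alts is not None and len(alts) > 1:
                if biallelic_only:
                    counters["skipped_multiallelic"] += 1
                    continue
            ref = record.ref
            alt = alts[0] if alts else None
            if biallelic_only and (
                alt is None
                or len(ref) != 1
                or len(alt) != 1
                or ref not in BASES
                or alt not in BASES
            ):
                counters["skipped_non_snv"] += 1
                continue

            data = record.samples[sample]
            gt = data.get("GT")
            missing_gt = gt is None or any(allele is None for allele in gt)
            ad = data.get("AD")
            dp = data.get("DP")
            gq = data.get("GQ")
            if not missing_gt and (ad is None or dp is None or gq is None):
                counters["skipped_missing_fields"] += 1
                continue

            ref_count = int(ad[0]) if ad and ad[0] is not None else 0
            alt_count = int(ad[1]) if ad and len(ad) > 1 and ad[1] is not None else 0
            total_dp = int(dp) if dp is not None else ref_count + alt_count
            support = ReadSupport(
                ref_count=ref_count,
                alt_count=alt_count,
                other_count=max(0, total_dp - ref_count - alt_count),
            )

            if missing_gt:
                genotype = Genotype.MISSING
            else:
                key = tuple(sorted(gt))
                genotype = _GT_FROM_ALLELES.get(key)
                if genotype is None:
                    counters["skipped_non_snv"] += 1
                    continue

            locus = Locus(
                chrom=record.chrom,
                pos=record.pos,
                ref_allele=ref,
                alt_allele=alt,
            )
            if locus in calls:
                counters["skipped_duplicate_locus"] += 1
                continue
            calls[locus] = GenotypeCall(
                locus=locus,
                genotype=genotype,
                support=support,
                gq=int(gq) if gq is not None else 0,
            )
            counters["retained"] += 1

    return SampleCallSet(
        sample_id=sample,
        replicate_id=replicate_id or path.stem,
        calls=calls,
        contig_lengths=contig_lengths,
        counters=counters,
    )


def write_vcf(callset: SampleCallSet, path: str | Path, *, source: str = "twinsnv") -> None:
    """Write one replicate call set as a single-sample VCFv4.2 text file.

    Records are emitted in (chrom, pos) order; genotype, AD, DP and GQ
    round-trip exactly through :func:`read_sample_calls`.
    """
    path = Path(path)
    lines = ["##fileformat=VCFv4.2", f"##source={source}"]
    for contig, length in sorted(callset.contig_lengths.items()):
        lines.append(f"##contig=<ID={contig},length={length}>")
    lines += [
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths for the ref and alt alleles">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + callset.sample_id,
    ]
    for locus in sorted(callset.calls, key=lambda l: l.sort_key):
        call = callset.calls[locus]
        support = call.support
        sample_field = (
            f"{_GT_TO_STRING[call.genotype]}:"
            f"{support.ref_count},{support.alt_count}:{support.dp}:{call.gq}"
        )
        lines.append(
            f"{locus.chrom}\t{locus.pos}\t.\t{locus.ref_allele}\t"
            f"{locus.alt_allele}\t.\t.\t.\tGT:AD:DP:GQ\t{sample_field}"
        )
    path.write_text("\n".join(lines) + "\n")


#: Column layout of the candidate (discordant-locus) table.  Per-replicate
#: values are comma-joined in replicate order within a single cell.
CANDIDATE_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "trace_genotype",
    "reference_genotype",
    "pattern",
    "trace_ref_counts",
    "trace_alt_counts",
    "trace_other_counts",
    "trace_gqs",
    "trace_hbs",
    "reference_ref_counts",
    "reference_alt_counts",
    "reference_other_counts",
    "reference_gqs",
    "reference_hbs",
]


def _hb_string(support: ReadSupport) -> str:
    if support.allelic_depth == 0:
        return "NA"
    return f"{support.alt_count / support.allelic_depth:.6f}"


def write_candidates(records: Iterable, path: str | Path) -> None:
    """Write discordant loci as a TSV, deterministically (chrom, pos) sorted.

    ``records`` are :class:`~twinsnv.discordance.DiscordantLocus` objects;
    the import is kept structural to avoid a module cycle.
    """
    ordered = sorted(records, key=lambda rec: rec.locus.sort_key)
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(CANDIDATE_COLUMNS)
        for rec in ordered:
            row = [
                rec.locus.chrom,
                rec.locus.pos,
                rec.locus.ref_allele,
                rec.locus.alt_allele,
                rec.trace_genotype.value,
                rec.reference_genotype.value,
                rec.pattern,
            ]
            for supports, gqs in (
                (rec.trace_support, rec.trace_gq),
                (rec.reference_support, rec.reference_gq),
            ):
                row.append(",".join(str(s.ref_count) for s in supports))
                row.append(",".join(str(s.alt_count) for s in supports))
                row.append(",".join(str(s.other_count) for s in supports))
                row.append(",".join(str(g) for g in gqs))
                row.append(",".join(_hb_string(s) for s in supports))
            writer.writerow(row)


def read_candidate_loci(path: str | Path) -> list[Locus]:
    """Parse the loci (first four columns) back out of a candidate TSV."""
    loci: list[Locus] = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            loci.append(
                Locus(
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    ref_allele=row["ref"],
                    alt_allele=row["alt"],
                )
            )
    return loci
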