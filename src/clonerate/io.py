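"""Readers and writers for allele-count tables, FASTQ, VCF and catalogs.

Internal coordinates are 0-based half-open; all user-facing TSV/VCF
positions are 1-based.  The allele-count TSV is long-format with the
documented header ``contig  pos  ref  alt  sample  ref_count  alt_count``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .subclonal import VariantSite

__all__ = [
    "ALLELE_COUNT_COLUMNS",
    "read_allele_counts",
    "write_allele_counts",
    "write_calls_tsv",
    "write_calls_vcf",
    "write_fastq_pairs",
    "write_catalog_tsv",
    "read_catalog_tsv",
    "config_hash",
]

ALLELE_COUNT_COLUMNS = ["contig", "pos", "ref", "alt", "sample", "ref_count", "alt_count"]


def read_allele_counts(path, format: str = "tsv") -> list[VariantSite]:
    """Load per-sample allele counts as :class:`VariantSite` records.

    ``format='tsv'`` expects the long-format header above; ``format='vcf'``
    reads per-sample AD (allele depth) fields, splitting multi-allelic
    records with a warning.  Positions are 1-based in both formats.
    """
    if format == "tsv":
        return _read_tsv(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown format {format!r}")


def _read_tsv(path) -> list[VariantSite]:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(ALLELE_COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = df[(df.ref_count < 0) | (df.alt_count < 0)]
    if not bad.empty:
        raise ValueError(f"{path}: negative counts at line {bad.index[0] + 2}")
    sites: dict[tuple, VariantSite] = {}
    for row in df.itertuples():
        key = (row.contig, int(row.pos), row.ref, row.alt)
        site = sites.get(key)
        if site is None:
            site = VariantSite(
                contig=str(row.contig), position=int(row.pos),
                ref=str(row.ref), alt=str(row.alt), counts={},
            )
            sites[key] = site
        site.counts[str(row.sample)] = (int(row.ref_count), int(row.alt_count))
    return list(sites.values())


def _read_vcf(path) -> list[VariantSite]:
    import warnings

    import pysam

    sites = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) > 1:
                warnings.warn(
                    f"{rec.chrom}:{rec.pos}: multi-allelic record split into "
                    f"{len(alts)} sites", stacklevel=2,
                )
            for ai, alt in enumerate(alts):
                counts = {}
                for s in samples:
                    ad = rec.samples[s].get("AD")
                    if ad is None or ad[0] is None:
                        raise ValueError(
                            f"{rec.chrom}:{rec.pos}: sample {s} lacks an AD field"
                        )
                    counts[s] = (int(ad[0]), int(ad[ai + 1]))
                sites.append(
                    VariantSite(
                        contig=rec.chrom, position=rec.pos,
                        ref=rec.ref, alt=alt, counts=counts,
                    )
                )
    return sites


def write_allele_counts(sites, path) -> None:
    """Write VariantSites as the long-format allele-count TSV (1-based)."""
    rows = [
        {
            "contig": s.contig, "pos": s.position, "ref": s.ref, "alt": s.alt,
            "sample": sample, "ref_count": rc, "alt_count": ac,
        }
        for s in sites
        for sample, (rc, ac) in s.counts.items()
    ]
    pd.DataFrame(rows, columns=ALLELE_COUNT_COLUMNS).to_csv(path, sep="\t", index=False)


def write_calls_tsv(calls, path) -> None:
    rows = [
        {
            "contig": c.site.contig, "pos": c.site.position,
            "ref": c.site.ref, "alt": c.site.alt,
            "statistic": c.statistic, "p_value": c.p_value,
            "p_adjusted": c.p_adjusted, "detected": c.detected,
            "clonality": c.clonality, "degenerate": c.degenerate,
        }
        for c in calls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_calls_vcf(calls, path, sample_id: str, control_id: str) -> None:
    """Minimal uncompressed VCF with the adjusted p-value in INFO/PADJ."""
    import pysam

    header = pysam.VariantHeader()
    contigs = sorted({c.site.contig for c in calls})
    for contig in contigs:
        header.contigs.add(contig, length=2 ** 29)
    header.info.add("PADJ", 1, "Float", "Bonferroni-adjusted chi-square p-value")
    header.info.add("CLON", 1, "String", "Clonality class by MAF")
    header.formats.add("AD", "R", "Integer", "Allele depths (ref, alt)")
    header.add_sample(sample_id)
    header.add_sample(control_id)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for c in sorted(calls, key=lambda c: (c.site.contig, c.site.position)):
            rec = out.new_record(
                contig=c.site.contig, start=c.site.position - 1,
                alleles=(c.site.ref, c.site.alt),
            )
            rec.info["PADJ"] = float(c.p_adjusted)
            rec.info["CLON"] = c.clonality
            for s in (sample_id, control_id):
                rec.samples[s]["AD"] = c.site.counts.get(s, (0, 0))
            out.write(rec)


def write_fastq_pairs(pairs, path1, path2) -> None:
    """Write simulated read pairs as phred+33 paired FASTQ files."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    def records(reads, quals):
        for pair, read, qual in zip(pairs, reads, quals):
            rec = SeqRecord(Seq(read), id=f"pair{pair.pair_id}", description="")
            rec.letter_annotations["phred_quality"] = [int(q) for q in qual]
            yield rec

    r1 = [p.read1 for p in pairs]
    q1 = [p.qual1 for p in pairs]
    r2 = [p.read2 for p in pairs]
    q2 = [p.qual2 for p in pairs]
    SeqIO.write(records(r1, q1), str(path1), "fastq")
    SeqIO.write(records(r2, q2), str(path2), "fastq")


def write_catalog_tsv(catalog, path) -> None:
    """96-row TSV keyed by channel label, one column per sample."""
    catalog.counts.T.rename_axis("channel").to_csv(path, sep="\t")


def read_catalog_tsv(path):
    from .spectra import SpectrumCatalog

    df = pd.read_csv(path, sep="\t", index_col=0)
    return SpectrumCatalog(df.T)


def config_hash(config: dict) -> str:
    """Stable short hash of an effective configuration, for provenance."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
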