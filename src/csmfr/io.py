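"""Readers and writers for the pipeline's on-disk formats.

VCF 4.2 per sample (via pysam), BED3+ for tracks/regions (0-based half-open
on disk, converted to the internal 1-based inclusive convention on read),
TSV for sample metadata and per-variant annotations.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .core import AnnotationTrack, GenomeSpec, GenomicRegion, Mutation

BASES = {"A", "C", "G", "T"}


def child_seed(seed: int, stage: int) -> int:
    """Deterministic per-stage child seed from one global seed.

    Children are drawn from ``numpy.random.SeedSequence(seed).spawn`` so each
    pipeline stage is independently reproducible; the value is folded below
    2**31 for portability as a plain integer seed.
    """
    ss = np.random.SeedSequence(seed).spawn(stage + 1)[stage]
    return int(ss.generate_state(1)[0] % (2**31))


def child_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, stage))


# ---------------------------------------------------------------------------
# VCF


def _vcf_header(genome: GenomeSpec, sample_id: str) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom, length in genome:
        header.contigs.add(chrom, length=length)
    header.info.add("DP", 1, "Integer", "Total read depth at the site")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Read depth per allele (ref, alt)")
    header.formats.add("DP", 1, "Integer", "Read depth at this position")
    header.filters.add("fail", None, None, "Failed caller-internal filters")
    header.add_sample(sample_id)
    return header


def write_vcf(
    mutations: Sequence[Mutation], path: str | os.PathLike, genome: GenomeSpec
) -> None:
    """Write one sample's calls as VCF 4.2 with DP and AD fields."""
    mutations = list(mutations)
    sample_ids = {m.sample_id for m in mutations}
    if len(sample_ids) > 1:
        raise ValueError(f"one VCF per sample; got samples {sorted(sample_ids)}")
    sample_id = sample_ids.pop() if sample_ids else Path(path).stem
    header = _vcf_header(genome, sample_id)
    order = {name: i for i, name in enumerate(genome.names)}
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for m in sorted(mutations, key=lambda m: (order.get(m.chrom, 1 << 30), m.pos)):
            rec = vcf.new_record(
                contig=m.chrom,
                start=m.pos - 1,
                alleles=(m.ref, m.alt),
                filter="PASS" if m.filter_flag == "PASS" else "fail",
            )
            rec.info["DP"] = m.depth
            rec.samples[sample_id]["GT"] = (0, 1)
            rec.samples[sample_id]["AD"] = (m.depth - m.alt_reads, m.alt_reads)
            rec.samples[sample_id]["DP"] = m.depth
            vcf.write(rec)


def read_vcf(
    path: str | os.PathLike, sample_id: str | None = None, group: str = ""
) -> list[Mutation]:
    """Read biallelic SNVs from a single-sample VCF.

    Multi-allelic records are split into one candidate per alternative
    allele; non-SNV alleles are discarded. 1-based positions are preserved.
    """
    out: list[Mutation] = []
    with pysam.VariantFile(str(path)) as vcf:
        vcf_samples = list(vcf.header.samples)
        if sample_id is None:
            sample_id = vcf_samples[0] if vcf_samples else Path(path).stem
        for rec in vcf:
            if rec.ref is None or rec.alts is None:
                continue
            if len(rec.ref) != 1 or rec.ref not in BASES:
                continue
            filter_keys = list(rec.filter.keys())
            flag = "PASS" if (not filter_keys or filter_keys == ["PASS"]) else filter_keys[0]
            sample_data = rec.samples[vcf_samples[0]] if vcf_samples else None
            ad = None
            if sample_data is not None and sample_data.get("AD") is not None:
                ad = sample_data["AD"]
            depth = None
            if sample_data is not None and sample_data.get("DP") is not None:
                depth = int(sample_data["DP"])
            elif "DP" in rec.info:
                depth = int(rec.info["DP"])
            for alt_index, alt in enumerate(rec.alts, start=1):
                if alt is None or len(alt) != 1 or alt not in BASES or alt == rec.ref:
                    continue
                alt_reads = None
                if ad is not None and len(ad) > alt_index and ad[alt_index] is not None:
                    alt_reads = int(ad[alt_index])
                if depth is None or alt_reads is None:
                    raise ValueError(
                        f"{path}: record {rec.chrom}:{rec.pos} lacks DP/AD fields"
                    )
                out.append(
                    Mutation(
                        sample_id=sample_id,
                        group=group,
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        depth=depth,
                        alt_reads=alt_reads,
                        filter_flag=flag,
                    )
                )
    return out


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | os.PathLike) -> list[GenomicRegion]:
    """Read BED3+ into 1-based inclusive regions; column 4 becomes ``cls``."""
    regions: list[GenomicRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start")
            cls = fields[3] if len(fields) > 3 else ""
            regions.append(GenomicRegion(chrom, start + 1, end, cls=cls))
    return regions


def write_bed(regions: Iterable[GenomicRegion], path: str | os.PathLike) -> None:
    """Write regions as BED (0-based half-open); no implicit merge or sort."""
    with open(path, "w") as fh:
        for r in regions:
            name = r.cls if r.cls else "."
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{name}\n")


def read_track(path: str | os.PathLike, name: str | None = None) -> AnnotationTrack:
    regions = read_bed(path)
    return AnnotationTrack(
        name or Path(path).stem, [(r.chrom, r.start - 1, r.end) for r in regions]
    )


def write_track(track: AnnotationTrack, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in track.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{track.name}\n")


# ---------------------------------------------------------------------------
# TSV tables


def write_metadata(metadata: pd.DataFrame, path: str | os.PathLike) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "group", "age"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata columns {sorted(missing)}")
    return df


def variant_id(chrom: str, pos: int, ref: str, alt: str) -> str:
    return f"{chrom}:{pos}:{ref}:{alt}"


def write_annotations(mutations: Sequence[Mutation], path: str | os.PathLike) -> None:
    """Per-variant annotation table (gnomAD AF, CADD, FATHMM), site-keyed."""
    rows = {}
    for m in mutations:
        rows[variant_id(*m.site_key)] = {
            "variant": variant_id(*m.site_key),
            "popmax_af": m.popmax_af,
            "cadd_phred": m.cadd_phred,
            "fathmm_class": m.fathmm_class,
        }
    pd.DataFrame(rows.values()).to_csv(path, sep="\t", index=False)


def read_annotations(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t").set_index("variant")


def attach_annotations(
    mutations: Sequence[Mutation], annotations: pd.DataFrame
) -> None:
    """Set popmax_af / cadd_phred / fathmm_class in place from the table."""
    for m in mutations:
        key = variant_id(*m.site_key)
        if key not in annotations.index:
            continue
        row = annotations.loc[key]
        m.popmax_af = None if pd.isna(row["popmax_af"]) else float(row["popmax_af"])
        m.cadd_phred = None if pd.isna(row["cadd_phred"]) else float(row["cadd_phred"])
        m.fathmm_class = None if pd.isna(row["fathmm_class"]) else str(row["fathmm_class"])


def write_genome_spec(genome: GenomeSpec, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome:
            fh.write(f"{chrom}\t{length}\n")


def read_genome_spec(path: str | os.PathLike) -> GenomeSpec:
    pairs = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, length = line.split("\t")[:2]
            pairs.append((chrom, int(length)))
    return GenomeSpec(pairs)


def mutations_to_frame(mutations: Sequence[Mutation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in mutations],
            "group": [m.group for m in mutations],
            "chrom": [m.chrom for m in mutations],
            "pos": [m.pos for m in mutations],
            "ref": [m.ref for m in mutations],
            "alt": [m.alt for m in mutations],
            "depth": [m.depth for m in mutations],
            "alt_reads": [m.alt_reads for m in mutations],
            "vaf": [m.vaf for m in mutations],
            "filter_flag": [m.filter_flag for m in mutations],
            "popmax_af": [m.popmax_af for m in mutations],
            "cadd_phred": [m.cadd_phred for m in mutations],
            "fathmm_class": [m.fathmm_class for m in mutations],
        }
    )


def write_mutations_tsv(mutations: Sequence[Mutation], path: str | os.PathLike) -> None:
    mutations_to_frame(mutations).to_csv(path, sep="\t", index=False)


def read_mutations_tsv(path: str | os.PathLike) -> list[Mutation]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str})
    out = []
    for row in df.itertuples(index=False):
        out.append(
            Mutation(
                sample_id=row.sample_id,
                group=row.group,
                chrom=row.chrom,
                pos=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                depth=int(row.depth),
                alt_reads=int(row.alt_reads),
                vaf=float(row.vaf),
                filter_flag=row.filter_flag,
                popmax_af=None if pd.isna(row.popmax_af) else float(row.popmax_af),
                cadd_phred=None if pd.isna(row.cadd_phred) else float(row.cadd_phred),
                fathmm_class=None
                if (isinstance(row.fathmm_class, float) and pd.isna(row.fathmm_class))
                else row.fathmm_class,
            )
        )
    return out
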