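"""Readers and writers for the pipeline's on-disk formats.

FASTA and FASTQ go through Biopython; the miRBase-dialect GFF3 of mature
coordinates (1-based inclusive, ``Name=`` attributes) and the various TSV
tables are handled with pandas. All formats are plain text.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord

from .align import Alignment, Mature, PreMiRNA
from .classify import SiteAnnotation, VariantRecord
from .errors import InputError
from .preprocess import UniqueRead
from .sitecall import CombinedSite, EditingSiteCall

GFF_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


# -- FASTA / FASTQ ----------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | os.PathLike) -> list[tuple[str, str, str]]:
    with open(path) as fh:
        return [(name, seq, qual) for name, seq, qual in FastqGeneralIterator(fh)]


def write_fastq(reads: Iterable[tuple[str, str, str]], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


# -- miRBase-style GFF3 -----------------------------------------------------

def write_mature_gff3(hairpins: Sequence[PreMiRNA], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for pm in hairpins:
            fh.write(
                f"{pm.id}\tmirledit\tmiRNA_primary_transcript\t1\t{len(pm.sequence)}"
                f"\t.\t+\t.\tID={pm.id};Name={pm.id}\n"
            )
            for m in pm.matures:
                fh.write(
                    f"{pm.id}\tmirledit\tmiRNA\t{m.start}\t{m.end}\t.\t+\t.\t"
                    f"ID={m.name};Name={m.name};Derives_from={pm.id}\n"
                )


def _parse_attributes(attrs: str) -> dict[str, str]:
    out = {}
    for field in attrs.strip().split(";"):
        if "=" in field:
            k, v = field.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_mature_gff3(path: str | os.PathLike) -> dict[str, list[Mature]]:
    """Mature annotations per hairpin id from a miRBase-dialect GFF3."""
    df = pd.read_csv(
        path, sep="\t", comment="#", names=GFF_COLUMNS, header=None, dtype=str
    )
    matures: dict[str, list[Mature]] = {}
    for _, row in df[df["type"] == "miRNA"].iterrows():
        attrs = _parse_attributes(row["attributes"])
        name = attrs.get("Name") or attrs.get("ID") or "unnamed"
        arm = "3p" if name.endswith("3p") else "5p"
        matures.setdefault(row["seqid"], []).append(
            Mature(name=name, arm=arm, start=int(row["start"]), end=int(row["end"]))
        )
    return matures


def load_reference(
    hairpin_fasta: str | os.PathLike,
    mature_gff3: str | os.PathLike,
    flank3_fasta: str | os.PathLike | None = None,
) -> list[PreMiRNA]:
    """Assemble PreMiRNA objects from FASTA + GFF3 (+ optional flank FASTA)."""
    seqs = read_fasta(hairpin_fasta)
    matures = read_mature_gff3(mature_gff3)
    flanks = read_fasta(flank3_fasta) if flank3_fasta else {}
    out = []
    for hid, seq in seqs.items():
        out.append(
            PreMiRNA(
                id=hid,
                sequence=seq,
                matures=matures.get(hid, []),
                flank3=flanks.get(hid, ""),
            )
        )
    return out


# -- TSV tables -------------------------------------------------------------

def unique_reads_to_df(reads: Sequence[UniqueRead]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"sequence": r.sequence, "raw_count": r.raw_count, "rptm": r.rptm,
             "min_phred": r.min_phred}
            for r in reads
        ]
    )


def df_to_unique_reads(df: pd.DataFrame) -> list[UniqueRead]:
    return [
        UniqueRead(
            sequence=row["sequence"],
            raw_count=int(row["raw_count"]),
            rptm=float(row["rptm"]),
            min_phred=int(row.get("min_phred", 30)),
        )
        for _, row in df.iterrows()
    ]


def alignments_to_df(alignments: Sequence[Alignment]) -> pd.DataFrame:
    rows = []
    for a in alignments:
        rows.append(
            {
                "read": a.read.sequence,
                "locus": a.locus_id,
                "start": a.start,
                "mismatches": ";".join(f"{p}:{r}>{alt}" for p, r, alt in a.mismatches),
                "tail": ";".join(f"{p}:{r}>{alt}" for p, r, alt in a.tail),
                "weight": a.weight,
            }
        )
    return pd.DataFrame(rows, columns=["read", "locus", "start", "mismatches", "tail", "weight"])


def calls_to_df(calls: Sequence[EditingSiteCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "key": c.key, "level": c.level, "support_raw": c.support_raw,
                "support_rptm": c.support_rptm, "coverage": c.coverage,
                "p_value": c.p_value, "q_value": c.q_value, "significant": c.significant,
            }
            for c in calls
        ]
    )


def combined_to_level_matrix(
    sites: Sequence[CombinedSite], retained_only: bool = True
) -> pd.DataFrame:
    """Site x sample editing-level matrix from combined sites."""
    rows = {}
    for s in sites:
        if retained_only and not s.retained:
            continue
        rows[s.key] = {sample: stat.level for sample, stat in s.per_sample.items()}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "site"
    return df.sort_index()


def annotations_to_df(annotations: Sequence[SiteAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "key": a.key, "category": a.category, "is_snp": a.is_snp,
                "is_conserved": a.is_conserved, "in_seed": a.in_seed,
                "context5": a.context5, "context3": a.context3,
                "mature": a.mature_name,
            }
            for a in annotations
        ]
    )


def read_design(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    required = {"sample", "group", "age"}
    if missing := required - set(df.columns):
        raise InputError(f"design table is missing columns: {sorted(missing)}")
    return df


def read_variants(path: str | os.PathLike) -> list[VariantRecord]:
    """Variant records from a TSV (chrom/pos/id/ref/alt header) or a
    plain-text VCF subset (first five columns)."""
    path = str(path)
    if path.endswith(".vcf"):
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, usecols=range(5),
            names=["chrom", "pos", "id", "ref", "alt"], dtype=str,
        )
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
        df.columns = [c.lower().lstrip("#") for c in df.columns]
    return [
        VariantRecord(
            chrom=str(row["chrom"]), position=int(row["pos"]),
            ref=row["ref"], alt=row["alt"], id=str(row.get("id", ".")),
        )
        for _, row in df.iterrows()
    ]
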