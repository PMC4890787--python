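"""Readers/writers for the pipeline's text interchange formats.

Sequences go through Biopython (FASTA/FASTQ); tables are plain CSV/TSV via
pandas; depth/MQ tracks are bedGraph-style TSV (0-based half-open, the only
place the package leaves 1-based inclusive coordinates); junctions export
as BEDPE-like TSV or VCF BND/DUP records; allele models as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from mbsv.svasm import BreakpointJunction, DerivedAlleleModel
from mbsv.syndata.genome import ToyGenome


def write_fasta(genomes: list[ToyGenome], path: str | Path) -> None:
    SeqIO.write([g.to_seqrecord() for g in genomes], str(path), "fasta")


def read_fasta(path: str | Path) -> list[ToyGenome]:
    return [
        ToyGenome(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fastq(reads, path: str | Path) -> None:
    SeqIO.write(reads, str(path), "fastq")


def read_fastq(path: str | Path):
    return list(SeqIO.parse(str(path), "fastq"))


def write_bedgraph(track: pd.DataFrame, path: str | Path, value_col: str = "depth") -> None:
    """Window track to bedGraph (converts to 0-based half-open starts)."""
    out = track[["chrom", "start", "end", value_col]].copy()
    out["start"] = out["start"] - 1
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path: str | Path, value_col: str = "depth") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", names=["chrom", "start", "end", value_col])
    df["start"] = df["start"] + 1
    return df


def junctions_to_bedpe(junctions: list[BreakpointJunction], chrom: str = "chrT") -> pd.DataFrame:
    rows = []
    for j in junctions:
        rows.append(
            {
                "chrom1": chrom,
                "start1": j.left_end - 1,
                "end1": j.left_end,
                "chrom2": chrom,
                "start2": j.right_start - 1,
                "end2": j.right_start,
                "name": f"jct_{j.left_end}_{j.right_start}",
                "score": j.support,
                "strand1": "+",
                "strand2": "+",
                "homology_len": j.homology_len,
                "inserted_seq": j.inserted_seq or ".",
            }
        )
    return pd.DataFrame(rows)


def junctions_to_vcf(
    junctions: list[BreakpointJunction], ref: ToyGenome, path: str | Path
) -> None:
    """Minimal VCF 4.2 with one BND record per junction side-A."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={ref.chrom_name},length={ref.length}>",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=MATEPOS,Number=1,Type=Integer,Description="Junction partner position">',
        '##INFO=<ID=HOMLEN,Number=1,Type=Integer,Description="Microhomology length">',
        '##INFO=<ID=INSSEQ,Number=1,Type=String,Description="Untemplated insertion">',
        '##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Supporting reads">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for i, j in enumerate(junctions):
        base = ref.sequence[j.left_end - 1]
        ins = j.inserted_seq
        alt = f"{base}{ins}[{ref.chrom_name}:{j.right_start}["
        info = (
            f"SVTYPE=BND;MATEPOS={j.right_start};HOMLEN={j.homology_len};"
            f"INSSEQ={ins or '.'};SUPPORT={j.support}"
        )
        lines.append(
            f"{ref.chrom_name}\t{j.left_end}\tbnd_{i}\t{base}\t{alt}\t.\tPASS\t{info}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def model_to_json(model: DerivedAlleleModel, path: str | Path | None = None) -> str:
    doc = {
        "insertion_after": model.insertion_after,
        "copies": [
            {
                "interval": list(c.interval),
                "copy_index": c.copy_index,
                "original": c.original,
            }
            for c in model.copies
        ],
        "junctions": [
            {
                "left_end": j.left_end,
                "right_start": j.right_start,
                "homology_len": j.homology_len,
                "inserted_seq": j.inserted_seq,
                "support": j.support,
            }
            for j in model.junctions
        ],
    }
    text = json.dumps(doc, indent=2)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
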