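"""File formats: FASTQ/FASTA via Biopython, TSV via pandas, minimal VCF."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from ._seq import phred_to_string
from .callvars import VariantCall

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "write_fastq_pair",
    "write_cs_records",
    "write_mapped_tsv",
    "write_vcf",
    "write_truth_vcf",
    "load_config",
]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, records: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_fastq(path) -> list[tuple[str, str, str]]:
    """[(id, sequence, Phred+33 quality string), ...]"""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = rec.letter_annotations["phred_quality"]
        out.append((rec.id, str(rec.seq).upper(), phred_to_string(quals)))
    return out


def write_fastq(path, records) -> None:
    """records: iterable of (id, sequence, quality-string-or-int-array)."""
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            if not isinstance(qual, str):
                qual = phred_to_string(qual)
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def write_fastq_pair(prefix, reads) -> tuple[Path, Path]:
    """Write a SimReads bundle to <prefix>_R1.fastq / <prefix>_R2.fastq."""
    p1 = Path(f"{prefix}_R1.fastq")
    p2 = Path(f"{prefix}_R2.fastq")
    write_fastq(p1, zip(reads.ids, reads.r1_seq, reads.r1_qual))
    write_fastq(p2, zip(reads.ids, reads.r2_seq, reads.r2_qual))
    return p1, p2


def write_cs_records(fasta_path, tsv_path, cs_list) -> None:
    """CS units as N-masked FASTA plus a sidecar TSV of per-CS evidence."""
    write_fasta(fasta_path, {cs.source_read_id or f"cs{i}": cs.unit
                             for i, cs in enumerate(cs_list)})
    rows = [
        {
            "cs_id": cs.source_read_id or f"cs{i}",
            "period": cs.period,
            "min_copies": int(cs.copy_count.min()) if len(cs.copy_count) else 0,
            "max_copies": int(cs.copy_count.max()) if len(cs.copy_count) else 0,
            "masked_positions": cs.unit.count("N"),
        }
        for i, cs in enumerate(cs_list)
    ]
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)


def write_mapped_tsv(path, mapped) -> None:
    rows = [
        {
            "cs_id": m.cs_id,
            "ref": m.ref_id,
            "start": m.start,
            "end": m.end,
            "strand": m.strand,
            "junction_offset": m.junction_offset,
            "edit_cost": m.edit_cost,
            "ops": m.alignment_ops,
        }
        for m in mapped
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##INFO=<ID=CS,Number=1,Type=Integer,Description="Supporting CS count">\n'
    '##INFO=<ID=DJ,Number=1,Type=Integer,Description="Distinct junction support">\n'
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="CS depth">\n'
    '##INFO=<ID=AF,Number=1,Type=Float,Description="Alt frequency">\n'
    '##FILTER=<ID=lowFreq,Description="Frequency below the minimum">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


def write_vcf(path, calls: list[VariantCall]) -> None:
    """Minimal VCF 4.2 for substitution calls (POS is 1-based)."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in calls:
            filt = "PASS" if c.passed_frequency_filter else "lowFreq"
            info = f"CS={c.cs_support};DJ={c.distinct_junction_support};DP={c.depth};AF={c.frequency:.6f}"
            fh.write(
                f"{c.ref_id}\t{c.position + 1}\t.\t{c.ref_base}\t{c.alt_base}\t.\t{filt}\t{info}\n"
            )


def write_truth_vcf(path, variants: pd.DataFrame, reference: str, ref_id: str = "ref") -> None:
    """Truth variants as minimal VCF; 1-bp indels are left-anchored."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _, row in variants.iterrows():
            pos = int(row["position"])
            if row["vtype"] == "SNP":
                ref, alt, vcf_pos = row["ref"], row["alt"], pos + 1
            elif row["vtype"] == "DEL":
                anchor = reference[pos - 1] if pos > 0 else reference[pos + 1]
                ref, alt, vcf_pos = anchor + row["ref"], anchor, pos
            else:  # INS before `pos`
                anchor = reference[pos - 1] if pos > 0 else reference[pos]
                ref, alt, vcf_pos = anchor, anchor + row["alt"], pos
            fh.write(f"{ref_id}\t{vcf_pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\n")


def load_config(path) -> dict:
    """Read a YAML or JSON pipeline/simulation config."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    import yaml

    return yaml.safe_load(text)
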