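"""Readers and writers for the plain-text formats used by the pipeline."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from tagdge.simulate import SimulationTruth
from tagdge.tagproc import TagCountTable, TagLedger


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=gid, description="") for gid, seq in records),
        str(path),
        "fasta",
    )


def write_fastq(reads, path, quality_char: str = "I") -> None:
    # bulk text write; a million 4-line records through SeqIO is too slow
    with open(path, "w") as fh:
        for i, read in enumerate(np.asarray(reads)):
            seq = read.decode() if isinstance(read, bytes) else str(read)
            fh.write(f"@read{i + 1}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_fastq(path) -> list[str]:
    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")]


def read_reads(path) -> list[str] | np.ndarray:
    """Read raw tags from FASTQ or a tag/count TSV (expanded by count)."""
    path = Path(path)
    if path.suffix.lower() in {".fq", ".fastq"}:
        return read_fastq(path)
    table = read_tag_table(path)
    return table.expand_reads()


def write_tag_table(table: TagCountTable, path, header_comments: Sequence[str] = ()) -> None:
    """Two-column tag/count TSV; the ledger rides along in '#' comments."""
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        fh.write(f"# library_id={table.library_id}\n")
        for key, value in table.ledger.as_dict().items():
            fh.write(f"# {key}={value}\n")
        fh.write("tag\tcount\n")
        for tag in sorted(table.entries):
            fh.write(f"{tag}\t{table.entries[tag]}\n")


def read_tag_table(path) -> TagCountTable:
    meta: dict[str, str] = {}
    entries: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = value.strip()
                continue
            if not line or line.startswith("tag\t"):
                continue
            tag, _, count = line.partition("\t")
            entries[tag] = int(count)
    ledger_keys = ("total_tags", "clean_tags", "singleton_tags", "retained_tags", "unique_tags")
    if all(k in meta for k in ledger_keys):
        ledger = TagLedger(**{k: int(meta[k]) for k in ledger_keys})
    else:
        retained = sum(entries.values())
        ledger = TagLedger(
            total_tags=retained,
            clean_tags=retained,
            singleton_tags=0,
            retained_tags=retained,
            unique_tags=len(entries),
        )
    return TagCountTable(
        library_id=meta.get("library_id", ""), entries=entries, ledger=ledger
    )


def write_ledger_json(ledger: TagLedger, path) -> None:
    with open(path, "w") as fh:
        json.dump(ledger.as_dict(), fh, indent=2)
        fh.write("\n")


def write_truth(truth: Iterable[SimulationTruth], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tbaseline_expr\tfold_change\tis_de\n")
        for t in truth:
            fh.write(f"{t.gene_id}\t{t.baseline_expr!r}\t{t.fold_change!r}\t{t.is_de}\n")


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["is_de"] = df["is_de"].astype(str).str.lower().isin({"true", "1"})
    return df


def read_ct_table(path) -> pd.DataFrame:
    """qPCR Ct CSV with columns sample, condition, gene, replicate, ct."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"condition", "gene", "ct"}
    if not required.issubset(df.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    return df


def write_frame(frame: pd.DataFrame, path, header_comments: Sequence[str] = ()) -> None:
    """TSV with optional leading '#' comment lines (seed, config hash)."""
    with open(path, "w") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_frame(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
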