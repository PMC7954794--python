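"""Readers and writers for the pipeline's plain-text exchange formats."""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .plates import GRID_COLUMNS, PlateGrid

PLATE_TSV_COLUMNS = ["plate", "bait", "condition", "timepoint_h"] + GRID_COLUMNS


def write_fasta(sequences: Mapping[str, str], path: str) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sequences.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(path, "fasta")}


def write_plates(plates: Sequence[PlateGrid], path: str) -> None:
    """Long-form TSV: one line per plate position with annotations."""
    frames = []
    for p in plates:
        df = p.df.copy()
        df.insert(0, "plate", p.plate_id)
        df.insert(1, "bait", p.bait)
        df.insert(2, "condition", p.condition)
        df.insert(3, "timepoint_h", p.timepoint_h)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_plates(path: str) -> list[PlateGrid]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for (plate_id, bait, condition), sub in df.groupby(
        ["plate", "bait", "condition"], dropna=False, sort=True
    ):
        tp = sub["timepoint_h"].iloc[0]
        out.append(PlateGrid(
            plate_id=str(plate_id),
            bait="" if pd.isna(bait) else str(bait),
            condition="" if pd.isna(condition) else str(condition),
            timepoint_h=None if pd.isna(tp) else float(tp),
            df=sub[GRID_COLUMNS].reset_index(drop=True),
        ))
    return out
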