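"""Plain-text readers/writers for the pipeline's external formats.

FASTA through Biopython; intervals as BED; coverage as a four-column
TSV (contig, pos, depth, proper_depth), one row per base; matrices as
TSV with row index.  All intervals are 0-based half-open, matching BED.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .discovery import CandidateSV, CoverageProfile, PavRecord

CATEGORY_COLORS = {  # itemRgb per PAV category
    "anchored_unique": "44,160,44",
    "anchored_ambiguous": "255,127,14",
    "incomplete": "31,119,180",
    "unanchored": "127,127,127",
}


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path, wrap: int = 60) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.FastaIO.FastaWriter(fh, wrap=wrap).write_file(records)


def write_candidates(candidates: Sequence[CandidateSV], path: str | Path) -> None:
    pd.DataFrame([{
        "id": c.id, "contig": c.contig, "start": c.start, "end": c.end,
        "caller_support": c.caller_support,
        "detected_in_self_mapping": int(c.detected_in_self_mapping),
    } for c in candidates]).to_csv(path, sep="\t", index=False)


def read_candidates(path: str | Path) -> list[CandidateSV]:
    df = pd.read_csv(path, sep="\t")
    return [CandidateSV(
        id=str(r["id"]), contig=str(r["contig"]), start=int(r["start"]), end=int(r["end"]),
        caller_support=int(r.get("caller_support", 0)),
        detected_in_self_mapping=bool(r.get("detected_in_self_mapping", 0)),
    ) for _, r in df.iterrows()]


def write_pav_bed(records: Sequence[PavRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            rgb = CATEGORY_COLORS.get(rec.category, "0,0,0")
            fh.write(f"{rec.contig}\t{rec.start}\t{rec.end}\t{rec.id}\t0\t+"
                     f"\t{rec.start}\t{rec.end}\t{rgb}\n")


def write_coverage(profiles: Mapping[str, CoverageProfile], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tpos\tdepth\tproper_depth\n")
        for name, prof in profiles.items():
            proper = (prof.properly_paired_depth if prof.properly_paired_depth is not None
                      else np.zeros(len(prof.depth), dtype=int))
            for i, (d, p) in enumerate(zip(prof.depth, proper)):
                fh.write(f"{name}\t{prof.start + i}\t{d}\t{p}\n")


def read_coverage(path: str | Path) -> dict[str, CoverageProfile]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, CoverageProfile] = {}
    for contig, sub in df.groupby("contig", sort=False):
        sub = sub.sort_values("pos")
        start, end = int(sub["pos"].iloc[0]), int(sub["pos"].iloc[-1]) + 1
        if len(sub) != end - start:
            raise ValueError(f"coverage for {contig} has gaps")
        out[contig] = CoverageProfile(
            contig=str(contig), start=start, end=end,
            depth=sub["depth"].to_numpy(),
            properly_paired_depth=sub["proper_depth"].to_numpy())
    return out


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
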