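"""Two-pseudomolecule pan-genome construction with an exact coordinate map.

Genotype-specific sequences that are absent from the reference are made
mappable by concatenating them into two extra pseudomolecules — one for
sequences anchored to the reference, one for unanchored/incomplete
sequences — each block separated by a run of 100 N.  The spacer keeps
short reads from aligning across block boundaries.  A bidirectional
coordinate map links pseudomolecule positions back to individual PAV
sequences so that per-region read counts can be attributed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["PanGenome", "SPACER", "build_pangenome", "map_to_pan", "map_from_pan",
           "write_pangenome_fasta", "write_coordinate_map", "read_coordinate_map"]

#: Sentinel returned by :func:`map_from_pan` for positions inside an N spacer.
SPACER = "__spacer__"

ANCHORED_NAME = "pav_anchored"
UNANCHORED_NAME = "pav_unanchored"


@dataclass
class PanGenome:
    reference: dict[str, str]
    pseudomolecules: dict[str, str]  # name -> sequence
    coordinate_map: pd.DataFrame     # pav_id, molecule, start, end (0-based half-open)
    spacer: int = 100

    def sequence_of(self, pav_id: str) -> str:
        row = self.coordinate_map.set_index("pav_id").loc[pav_id]
        return self.pseudomolecules[row["molecule"]][row["start"] : row["end"]]


def _concatenate(entries: Sequence[tuple[str, str]], molecule: str, spacer: int):
    parts, rows, offset = [], [], 0
    for i, (pav_id, seq) in enumerate(entries):
        if i > 0:
            parts.append("N" * spacer)
            offset += spacer
        parts.append(seq)
        rows.append({"pav_id": pav_id, "molecule": molecule,
                     "start": offset, "end": offset + len(seq)})
        offset += len(seq)
    return "".join(parts), rows


def build_pangenome(
    reference: Mapping[str, str],
    anchored: Sequence[tuple[str, str]],
    unanchored: Sequence[tuple[str, str]] = (),
    spacer: int = 100,
) -> PanGenome:
    """Assemble reference + anchored/unanchored pseudomolecules.

    ``anchored`` and ``unanchored`` are ordered (pav_id, sequence) pairs;
    anchored sequences should be supplied in reference-position order,
    unanchored ones keep their input order.  An empty unanchored set
    omits that pseudomolecule entirely.  Duplicate ids or empty
    sequences are rejected.
    """
    if spacer < 0:
        raise ValueError("spacer must be non-negative")
    entries = list(anchored) + list(unanchored)
    if not entries:
        raise ValueError("no genotype-specific sequences supplied")
    ids = [pav_id for pav_id, _ in entries]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate PAV ids: {dupes}")
    for pav_id, seq in entries:
        if not seq:
            raise ValueError(f"empty sequence for {pav_id}")
        if "N" in seq.upper():
            raise ValueError(f"{pav_id}: mapped intervals must contain no N")

    pseudomolecules: dict[str, str] = {}
    rows: list[dict] = []
    if anchored:
        seq, r = _concatenate(list(anchored), ANCHORED_NAME, spacer)
        pseudomolecules[ANCHORED_NAME] = seq
        rows.extend(r)
    if unanchored:
        seq, r = _concatenate(list(unanchored), UNANCHORED_NAME, spacer)
        pseudomolecules[UNANCHORED_NAME] = seq
        rows.extend(r)
    coord = pd.DataFrame(rows, columns=["pav_id", "molecule", "start", "end"])
    return PanGenome(reference=dict(reference), pseudomolecules=pseudomolecules,
                     coordinate_map=coord, spacer=spacer)


def map_to_pan(pg: PanGenome, pav_id: str, offset: int) -> tuple[str, int]:
    """Map an offset within a PAV sequence to a pseudomolecule position."""
    cmap = pg.coordinate_map
    hit = cmap[cmap["pav_id"] == pav_id]
    if hit.empty:
        raise KeyError(f"unknown PAV id {pav_id!r}")
    row = hit.iloc[0]
    if not (0 <= offset < row["end"] - row["start"]):
        raise ValueError(f"offset {offset} outside {pav_id} of length {row['end'] - row['start']}")
    return row["molecule"], int(row["start"] + offset)


def map_from_pan(pg: PanGenome, molecule: str, position: int) -> tuple[str, int] | str:
    """Map a pseudomolecule position back to (pav_id, offset), or SPACER."""
    if molecule not in pg.pseudomolecules:
        raise KeyError(f"unknown pseudomolecule {molecule!r}")
    if not (0 <= position < len(pg.pseudomolecules[molecule])):
        raise ValueError(f"position {position} outside {molecule}")
    cmap = pg.coordinate_map
    sub = cmap[cmap["molecule"] == molecule]
    hit = sub[(sub["start"] <= position) & (position < sub["end"])]
    if hit.empty:
        return SPACER
    row = hit.iloc[0]
    return row["pav_id"], int(position - row["start"])


def write_pangenome_fasta(pg: PanGenome, path: str | Path, wrap: int = 60) -> None:
    """Reference records followed by the pseudomolecules, 60-column wrapped."""
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in pg.reference.items()]
    records += [SeqRecord(Seq(seq), id=name, description="")
                for name, seq in pg.pseudomolecules.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)


def write_coordinate_map(pg: PanGenome, path: str | Path) -> None:
    pg.coordinate_map.to_csv(path, sep="\t", index=False)


def read_coordinate_map(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
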