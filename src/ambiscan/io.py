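"""File-format frontends: FASTA, Vienna dot-bracket, band matrices, reports."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .fingerprint import BandMatrix
from .scan import AmbiguousSequence, DiversityCensus, SiteRecord
from .structure import SecondaryStructure, parse_dotbracket


def read_fasta(path, coordinate_offset: int = 1) -> list[AmbiguousSequence]:
    records = [
        AmbiguousSequence(
            id=rec.id, residues=str(rec.seq), coordinate_offset=coordinate_offset
        )
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return records


def write_fasta(seqs: Sequence[AmbiguousSequence | tuple[str, str]], path) -> None:
    records = []
    for s in seqs:
        if isinstance(s, AmbiguousSequence):
            records.append(SeqRecord(Seq(s.residues), id=s.id, description=""))
        else:
            name, residues = s
            records.append(SeqRecord(Seq(residues), id=name, description=""))
    SeqIO.write(records, str(path), "fasta")


def read_vienna(path) -> tuple[AmbiguousSequence, SecondaryStructure]:
    """Read a Vienna file: optional '>name' line, sequence line, structure line."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    name = "structure"
    if lines and lines[0].startswith(">"):
        name = lines[0][1:].split()[0] or name
        lines = lines[1:]
    if len(lines) < 2:
        raise ValueError(f"Vienna file {path} needs a sequence line and a structure line")
    seq = AmbiguousSequence(id=name, residues=lines[0])
    struct = parse_dotbracket(lines[1].split()[0])
    if len(seq) != len(struct):
        raise ValueError(
            f"sequence length {len(seq)} != structure length {len(struct)} in {path}"
        )
    return seq, struct


def read_band_matrix(path) -> BandMatrix:
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return BandMatrix.read_csv(path, sep=sep)


def sites_to_frame(records: Sequence[SiteRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "position": [r.position for r in records],
            "union": ["".join(sorted(r.observed)) for r in records],
            "morphism": [r.morphism for r in records],
            "substitution_type": [r.substitution or "" for r in records],
            "indel_flag": [int(r.is_indel_column) for r in records],
        }
    )


def write_sites_tsv(records: Sequence[SiteRecord], path) -> None:
    sites_to_frame(records).to_csv(path, sep="\t", index=False)


def write_census_json(census: DiversityCensus, path) -> None:
    Path(path).write_text(json.dumps(census.as_dict(), indent=2, sort_keys=True) + "\n")
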