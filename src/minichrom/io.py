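"""Readers and writers for the standard formats the pipeline consumes and emits.

FASTA goes through Biopython; tabular formats (BED, bedGraph, TSV) through
pandas.  Coordinates are 0-based half-open throughout, matching BED.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motif import CbsHit
from .partition import Section
from .fate import CoverageTrack

__all__ = [
    "read_fasta",
    "write_fasta",
    "hits_to_bed",
    "read_hits_bed",
    "sections_to_bed",
    "read_intervals_bed",
    "write_bedgraph",
    "read_bedgraph",
    "read_genes",
]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def hits_to_bed(hits: Sequence[CbsHit], path=None) -> pd.DataFrame:
    """BED6: name = observed 15-mer (G strand), score = substitution class."""
    df = pd.DataFrame(
        {
            "chrom": [h.contig_id for h in hits],
            "start": [h.start for h in hits],
            "end": [h.end for h in hits],
            "name": [h.observed for h in hits],
            "score": [h.substitution_class for h in hits],
            "strand": [h.strand for h in hits],
        }
    )
    if path is not None:
        df.to_csv(path, sep="\t", header=False, index=False)
    return df


def read_hits_bed(path) -> list[CbsHit]:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    return [
        CbsHit(
            contig_id=str(r.chrom),
            start=int(r.start),
            strand=str(r.strand),
            observed=str(r.name),
            substitution_class=int(r.score),
        )
        for r in df.itertuples()
    ]


def sections_to_bed(sections: Sequence[Section], path=None) -> pd.DataFrame:
    """BED with name, bounded class and fate columns."""
    df = pd.DataFrame(
        {
            "chrom": [s.contig_id for s in sections],
            "start": [s.start for s in sections],
            "end": [s.end for s in sections],
            "name": [s.name for s in sections],
            "bounded_class": [s.bounded_class for s in sections],
            "fate": [s.fate for s in sections],
        }
    )
    if path is not None:
        df.to_csv(path, sep="\t", header=False, index=False)
    return df


def read_intervals_bed(path) -> dict[str, list[tuple[int, int]]]:
    """Contig -> [(start, end), ...] from the first three BED columns."""
    df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2],
                     names=["chrom", "start", "end"])
    out: dict[str, list[tuple[int, int]]] = {}
    for r in df.itertuples():
        out.setdefault(str(r.chrom), []).append((int(r.start), int(r.end)))
    for ivs in out.values():
        ivs.sort()
    return out


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Run-length compressed bedGraph of a per-base track."""
    with open(path, "w") as fh:
        for cid, arr in track.data.items():
            if len(arr) == 0:
                continue
            change = np.nonzero(np.diff(arr))[0] + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                fh.write(f"{cid}\t{s}\t{e}\t{arr[s]:g}\n")


def read_bedgraph(path, contig_lengths: Mapping[str, int],
                  sample_label: str = "") -> CoverageTrack:
    """Expand a bedGraph into per-base arrays over the given contig sizes."""
    data = {cid: np.zeros(n) for cid, n in contig_lengths.items()}
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"])
    for r in df.itertuples():
        cid = str(r.chrom)
        if cid in data:
            data[cid][int(r.start) : int(r.end)] = float(r.value)
    return CoverageTrack(data=data, sample_label=sample_label)


def read_genes(path) -> list[tuple[str, int, int, str]]:
    """Gene intervals from BED (cols 1-4) or GFF3 (type == gene).

    Returns (contig, start, end, gene_id) with 0-based half-open coordinates.
    """
    path = Path(path)
    genes: list[tuple[str, int, int, str]] = []
    if path.suffix.lower() in {".gff", ".gff3"}:
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9 or f[2] != "gene":
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                )
                gid = attrs.get("ID", f"{f[0]}:{f[3]}-{f[4]}")
                genes.append((f[0], int(f[3]) - 1, int(f[4]), gid))
    else:
        df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1, 2, 3],
                         names=["chrom", "start", "end", "name"])
        for r in df.itertuples():
            genes.append((str(r.chrom), int(r.start), int(r.end), str(r.name)))
    return genes
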