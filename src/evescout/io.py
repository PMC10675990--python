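"""Shared readers and writers for the handful of plain-text formats the pipeline speaks.

Coordinates are 0-based, half-open everywhere in memory and in BED output.
The two dialects that are 1-based on disk — samtools-style per-base depth
tables and GFF3 — are converted on read/write so no other module ever sees
a 1-based coordinate.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

HITS_COLUMNS = ["scaffold", "start", "end", "strand", "marker", "clade", "score"]
ALLELE_COLUMNS = ["scaffold", "pos", "ref_count", "alt_count"]
BED6_COLUMNS = ["scaffold", "start", "end", "name", "score", "strand"]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | os.PathLike) -> Dict[str, str]:
    """Read a FASTA file into an ordered {name: sequence} mapping (uppercased)."""
    genome: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        genome[rec.id] = str(rec.seq).upper()
    if not genome:
        raise ValueError(f"no sequences found in FASTA file {path!r}")
    return genome


def write_fasta(genome: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Depth tables: 3 columns (scaffold, pos, depth), pos 1-based on disk

def write_depth_tsv(depths: Mapping[str, np.ndarray], path: str | os.PathLike) -> None:
    frames = []
    for scaffold, track in depths.items():
        frames.append(pd.DataFrame({
            "scaffold": scaffold,
            "pos": np.arange(1, len(track) + 1),
            "depth": np.asarray(track, dtype=int),
        }))
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["scaffold", "pos", "depth"])
    table.to_csv(path, sep="\t", index=False, header=False)


def read_depth_tsv(path: str | os.PathLike,
                   lengths: Optional[Mapping[str, int]] = None) -> Dict[str, np.ndarray]:
    """Read a per-base depth table into {scaffold: depth array} (0-based index).

    Positions absent from the file are depth 0. ``lengths`` fixes array sizes;
    without it each array extends to the largest position seen.
    """
    table = pd.read_csv(path, sep="\t", header=None,
                        names=["scaffold", "pos", "depth"],
                        dtype={"scaffold": str, "pos": np.int64, "depth": np.int64})
    out: Dict[str, np.ndarray] = {}
    for scaffold, group in table.groupby("scaffold", sort=False):
        n = int(lengths[scaffold]) if lengths is not None else int(group["pos"].max())
        track = np.zeros(n, dtype=np.int64)
        track[group["pos"].to_numpy() - 1] = group["depth"].to_numpy()
        out[str(scaffold)] = track
    if lengths is not None:
        for scaffold, n in lengths.items():
            out.setdefault(str(scaffold), np.zeros(int(n), dtype=np.int64))
    return out


# ---------------------------------------------------------------------------
# Marker hit tables

def write_hits_tsv(hits: pd.DataFrame, path: str | os.PathLike) -> None:
    hits.loc[:, HITS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_hits_tsv(path: str | os.PathLike) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"scaffold": str, "marker": str, "clade": str})
    missing = [c for c in HITS_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"hit table {path!r} is missing columns {missing}")
    return table.loc[:, HITS_COLUMNS]


def read_blast_tabular(path: str | os.PathLike,
                       marker_clades: Mapping[str, str]) -> pd.DataFrame:
    """Read 12-column BLAST tabular output as a hit table.

    The query id is taken as the marker name; ``marker_clades`` maps marker
    names to clade labels (missing markers become ``unknown``). Subject
    coordinates are converted from 1-based inclusive to 0-based half-open.
    """
    cols = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore"]
    raw = pd.read_csv(path, sep="\t", header=None, names=cols)
    sstart = raw[["sstart", "send"]].min(axis=1) - 1
    send = raw[["sstart", "send"]].max(axis=1)
    strand = np.where(raw["send"] >= raw["sstart"], "+", "-")
    return pd.DataFrame({
        "scaffold": raw["sseqid"].astype(str),
        "start": sstart.astype(int),
        "end": send.astype(int),
        "strand": strand,
        "marker": raw["qseqid"].astype(str),
        "clade": [marker_clades.get(q, "unknown") for q in raw["qseqid"]],
        "score": raw["bitscore"].astype(float),
    })


# ---------------------------------------------------------------------------
# Allele count tables

def write_allele_counts_tsv(table: pd.DataFrame, path: str | os.PathLike) -> None:
    table.loc[:, ALLELE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_allele_counts_tsv(path: str | os.PathLike) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"scaffold": str})
    missing = [c for c in ALLELE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"allele count table {path!r} is missing columns {missing}")
    return table.loc[:, ALLELE_COLUMNS]


# ---------------------------------------------------------------------------
# BED6 / GFF3

def write_bed6(rows: Iterable[Tuple[str, int, int, str, float, str]],
               path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for scaffold, start, end, name, score, strand in rows:
            fh.write(f"{scaffold}\t{start}\t{end}\t{name}\t{score:g}\t{strand}\n")


def read_bed6(path: str | os.PathLike) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", header=None, comment="#")
    table = table.iloc[:, : len(BED6_COLUMNS)]
    table.columns = BED6_COLUMNS[: table.shape[1]]
    for col, default in (("name", "."), ("score", 0.0), ("strand", ".")):
        if col not in table.columns:
            table[col] = default
    table["scaffold"] = table["scaffold"].astype(str)
    return table


def write_gff3(features: Sequence[dict], path: str | os.PathLike,
               source: str = "evescout") -> None:
    """Write features (0-based half-open ``start``/``end``) as GFF3 (1-based inclusive).

    Each feature dict: scaffold, start, end, type, id, optional parent, strand,
    extra attribute pairs under ``attributes``.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for feat in features:
            attrs = [f"ID={feat['id']}"]
            if feat.get("parent"):
                attrs.append(f"Parent={feat['parent']}")
            for key, val in feat.get("attributes", {}).items():
                attrs.append(f"{key}={val}")
            fh.write("\t".join([
                feat["scaffold"], source, feat["type"],
                str(feat["start"] + 1), str(feat["end"]),
                ".", feat.get("strand", "."), ".", ";".join(attrs),
            ]) + "\n")
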