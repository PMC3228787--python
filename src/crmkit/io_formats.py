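"""Readers/writers for the formats the pipeline touches, with fixed coordinate conventions.

All internal coordinates are 0-based half-open.  Coordinates printed in
published region tables (1-based inclusive) are converted on input with
``start - 1, end``; :func:`region_from_one_based` performs that conversion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """Raised for malformed input files."""


class SetLabel(str, Enum):
    BACKGROUND = "background"
    MUSCLE = "muscle"
    NON_MUSCLE = "non_muscle"


@dataclass
class GenomicRegion:
    """A labeled half-open genomic interval.

    ``start``/``end`` are 0-based half-open base-pair coordinates;
    ``set_label`` records which study set the region belongs to and
    ``responder`` whether it validated in the reporter assay (``None``
    when untested).
    """

    chrom: str
    start: int
    end: int
    region_id: str = ""
    set_label: SetLabel | None = None
    responder: bool | None = None
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"degenerate region {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicRegion") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


def region_from_one_based(chrom: str, start1: int, end1: int, **kwargs) -> GenomicRegion:
    """Build a region from 1-based inclusive coordinates as printed in tables."""
    return GenomicRegion(chrom, start1 - 1, end1, **kwargs)


@dataclass
class PFM:
    """Position frequency matrix: base counts over the alphabet A, C, G, T."""

    motif_id: str
    name: str
    counts: np.ndarray  # shape (4, L)

    ALPHABET = "ACGT"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise FormatError(f"{self.motif_id}: counts must be 4 x L")
        if self.counts.shape[1] < 4:
            raise FormatError(f"{self.motif_id}: motif shorter than 4 columns")
        if np.any(self.counts < 0):
            raise FormatError(f"{self.motif_id}: negative counts")
        if np.any(self.counts.sum(axis=0) <= 0):
            raise FormatError(f"{self.motif_id}: empty column")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    def frequencies(self) -> np.ndarray:
        """Column-normalized base frequencies (4 x L)."""
        return self.counts / self.counts.sum(axis=0, keepdims=True)

    def consensus(self) -> str:
        return "".join(self.ALPHABET[i] for i in self.counts.argmax(axis=0))

    def reverse_complement(self) -> "PFM":
        return PFM(self.motif_id, self.name, self.counts[::-1, ::-1].copy())


@dataclass
class ScoreTrack:
    """Per-base conservation scores over a contiguous coordinate range.

    ``kind`` is ``bounded01`` for probability-like scores in [0, 1]
    (phastCons-style) or ``unbounded`` for rate-departure scores that may
    be negative (phyloP-style).
    """

    chrom: str
    start: int
    values: np.ndarray
    kind: str = "bounded01"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("bounded01", "unbounded"):
            raise ValueError(f"unknown track kind {self.kind!r}")
        if self.kind == "bounded01" and self.values.size and (
            self.values.min() < 0 or self.values.max() > 1
        ):
            raise ValueError("bounded01 track has values outside [0, 1]")

    @property
    def end(self) -> int:
        return self.start + len(self.values)

    def slice(self, start: int, end: int) -> np.ndarray:
        """Per-base values over [start, end); positions outside the track raise."""
        if start < self.start or end > self.end or start >= end:
            raise ValueError(f"[{start}, {end}) outside track [{self.start}, {self.end})")
        return self.values[start - self.start : end - self.start]


@dataclass
class PeakSet:
    """A named collection of (possibly overlapping) half-open peak intervals per chromosome."""

    name: str
    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, ivals in self.intervals.items():
            for s, e in ivals:
                if s >= e:
                    raise ValueError(f"degenerate peak {chrom}:{s}-{e}")

    def add(self, chrom: str, start: int, end: int) -> None:
        if start >= end:
            raise ValueError(f"degenerate peak {chrom}:{start}-{end}")
        self.intervals.setdefault(chrom, []).append((start, end))

    def n_peaks(self) -> int:
        return sum(len(v) for v in self.intervals.values())


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {sequence_id: uppercase sequence}.

    Sequences are uppercased; only A/C/G/T/N are accepted.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: empty or malformed FASTA")
    out: dict[str, str] = {}
    for rec in records:
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: empty sequence for {rec.id}")
        bad = set(seq) - set("ACGTN")
        if bad:
            raise FormatError(f"{path}: illegal characters {sorted(bad)} in {rec.id}")
        out[rec.id] = seq
    return out


def write_fasta(path: str | Path, sequences: dict[str, str], width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# BED

def read_bed(path: str | Path) -> list[GenomicRegion]:
    """Read BED3+ into regions (0-based half-open, as BED is defined).

    Column 4, when present, becomes ``region_id``; extra columns are kept in
    ``attributes['extra']``.  Records with start >= end are rejected with a
    warning rather than aborting the load.
    """
    regions: list[GenomicRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start_s, end_s = parts[0], parts[1], parts[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                warnings.warn(f"{path}:{lineno}: rejected degenerate interval {chrom}:{start}-{end}")
                continue
            region_id = parts[3] if len(parts) > 3 else f"{chrom}:{start}-{end}"
            attrs = {"extra": parts[4:]} if len(parts) > 4 else {}
            regions.append(GenomicRegion(chrom, start, end, region_id=region_id, attributes=attrs))
    return regions


def write_bed(path: str | Path, regions: Iterable[GenomicRegion]) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fields = [r.chrom, str(r.start), str(r.end), r.region_id]
            fields.extend(str(x) for x in r.attributes.get("extra", ()))
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# JASPAR flat PFM format (2008 dialect):
#   >MA0001 name
#   A  [ 1  2  3 ]
#   C  [ 4  5  6 ]  ... (bracket-less count rows also accepted)

def read_jaspar_pfm(path: str | Path) -> list[PFM]:
    """Parse JASPAR 4-line flat count matrices."""
    pfms: list[PFM] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        header = lines[i]
        if not header.startswith(">"):
            raise FormatError(f"{path}: expected '>' header, got {header!r}")
        toks = header[1:].split(None, 1)
        motif_id = toks[0] if toks else ""
        name = toks[1].strip() if len(toks) > 1 else motif_id
        rows: dict[str, list[float]] = {}
        for j in range(4):
            if i + 1 + j >= len(lines):
                raise FormatError(f"{path}: truncated matrix for {motif_id}")
            row = lines[i + 1 + j]
            base, _, rest = row.partition(" ")
            base = base.strip().upper()
            if base not in "ACGT":
                raise FormatError(f"{path}: unknown alphabet row {base!r} in {motif_id}")
            rest = rest.replace("[", " ").replace("]", " ")
            rows[base] = [float(x) for x in rest.split()]
        lengths = {len(v) for v in rows.values()}
        if len(rows) != 4 or len(lengths) != 1:
            raise FormatError(f"{path}: ragged matrix for {motif_id}")
        counts = np.array([rows[b] for b in "ACGT"])
        pfms.append(PFM(motif_id, name, counts))
        i += 5
    if not pfms:
        raise FormatError(f"{path}: no matrices found")
    return pfms


def write_jaspar_pfm(path: str | Path, pfms: Sequence[PFM]) -> None:
    with open(path, "w") as fh:
        for pfm in pfms:
            fh.write(f">{pfm.motif_id} {pfm.name}\n")
            for bi, base in enumerate("ACGT"):
                vals = " ".join(f"{v:g}" for v in pfm.counts[bi])
                fh.write(f"{base} [ {vals} ]\n")


# ---------------------------------------------------------------------------
# bedGraph score tracks

def read_score_track(path: str | Path, kind: str = "bounded01") -> ScoreTrack:
    """Expand a single-chromosome bedGraph into per-base scores.

    Intervals must be non-overlapping; gaps between intervals are filled
    with 0.
    """
    chrom = None
    ivals: list[tuple[int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: bedGraph needs 4 columns")
            c, s, e, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if chrom is None:
                chrom = c
            elif c != chrom:
                raise FormatError(f"{path}:{lineno}: multiple chromosomes in one track")
            if s >= e:
                raise FormatError(f"{path}:{lineno}: degenerate interval")
            ivals.append((s, e, v))
    if not ivals:
        raise FormatError(f"{path}: empty bedGraph")
    ivals.sort()
    for (s1, e1, _), (s2, _, _) in zip(ivals, ivals[1:]):
        if s2 < e1:
            raise FormatError(f"{path}: overlapping bedGraph intervals at {chrom}:{s2}")
    start, end = ivals[0][0], ivals[-1][1]
    values = np.zeros(end - start)
    for s, e, v in ivals:
        values[s - start : e - start] = v
    return ScoreTrack(chrom, start, values, kind=kind)


def write_score_track(path: str | Path, track: ScoreTrack) -> None:
    """Write a track as bedGraph, run-length encoding constant stretches."""
    with open(path, "w") as fh:
        vals = track.values
        i = 0
        while i < len(vals):
            j = i
            while j + 1 < len(vals) and vals[j + 1] == vals[i]:
                j += 1
            fh.write(f"{track.chrom}\t{track.start + i}\t{track.start + j + 1}\t{vals[i]:g}\n")
            i = j + 1


# ---------------------------------------------------------------------------
# Plate-reader CSV

PLATE_COLUMNS = [
    "clone_id",
    "insert_id",
    "set_label",
    "phase",
    "cell_type",
    "tech_rep",
    "firefly_lru",
    "renilla_lru",
]

CELL_TYPES = ("fibroblast", "myoblast", "myotube")


def read_plate_csv(path: str | Path) -> pd.DataFrame:
    """Read dual-luciferase plate measurements.

    Required columns: clone_id, insert_id, set_label, phase, cell_type,
    tech_rep, firefly_lru, renilla_lru.  LRUs must be finite and
    nonnegative.
    """
    df = pd.read_csv(path)
    missing = set(PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing plate columns {sorted(missing)}")
    for col in ("firefly_lru", "renilla_lru"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or np.isinf(vals).any() or (vals < 0).any():
            raise FormatError(f"{path}: {col} must be finite and nonnegative")
        df[col] = vals.astype(float)
    bad_ct = set(df["cell_type"]) - set(CELL_TYPES)
    if bad_ct:
        raise FormatError(f"{path}: unknown cell types {sorted(bad_ct)}")
    return df[PLATE_COLUMNS].copy()


def write_plate_csv(path: str | Path, wells: pd.DataFrame) -> None:
    wells[PLATE_COLUMNS].to_csv(path, index=False)
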