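"""Readers and writers for the file formats the pipeline touches.

All genomic coordinates are 0-based half-open (BED convention) throughout the
package. Peak files are BED3 or 10-column ENCODE narrowPeak; motifs are
exchanged in MEME minimal format; variants travel as a four-column TSV
(``chrom  pos  ref  alt`` with 0-based ``pos``).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, List, Mapping, Optional, Sequence, Union

import numpy as np

__all__ = [
    "GenomicInterval",
    "PeakRecord",
    "VariantRecord",
    "ParseError",
    "read_narrowpeak",
    "write_narrowpeak",
    "open_genome",
    "fetch_sequence",
    "chrom_sizes",
    "write_meme",
    "read_meme",
    "read_variants",
    "write_variants",
]

NUCLEOTIDES = "ACGT"


class ParseError(ValueError):
    """A malformed line in a peak/variant file."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass(frozen=True)
class PeakRecord:
    """One peak-file line: an interval plus its fold-enrichment signal.

    The optional fields mirror the remaining ENCODE narrowPeak columns.
    """

    interval: GenomicInterval
    signal_value: float = 1.0
    name: str = "."
    score: int = 0
    strand: str = "."
    p_value: float = -1.0
    q_value: float = -1.0
    summit: int = -1

    def __post_init__(self) -> None:
        if self.signal_value < 0:
            raise ValueError(f"signal_value must be >= 0, got {self.signal_value}")


@dataclass(frozen=True)
class VariantRecord:
    """A single-nucleotide variant; ``pos`` is 0-based."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        for allele, label in ((self.ref, "ref"), (self.alt, "alt")):
            if allele not in set(NUCLEOTIDES):
                raise ValueError(f"{label} allele must be one of A/C/G/T, got {allele!r}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ, both are {self.ref!r}")


# ---------------------------------------------------------------------------
# BED / narrowPeak
# ---------------------------------------------------------------------------

def read_narrowpeak(path: Union[str, os.PathLike]) -> List[PeakRecord]:
    """Read a BED3 or 10-column ENCODE narrowPeak file.

    Three-column lines get ``signal_value = 1.0``; ten-column lines take the
    fold enrichment from column 7 (1-based). Records come back in file order.
    """
    records: List[PeakRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            try:
                interval = GenomicInterval(chrom, start, end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if len(fields) >= 10:
                try:
                    records.append(
                        PeakRecord(
                            interval,
                            signal_value=float(fields[6]),
                            name=fields[3],
                            score=int(float(fields[4])),
                            strand=fields[5],
                            p_value=float(fields[7]),
                            q_value=float(fields[8]),
                            summit=int(fields[9]),
                        )
                    )
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: malformed narrowPeak columns") from exc
            else:
                records.append(PeakRecord(interval))
    return records


def write_narrowpeak(records: Iterable[PeakRecord], path: Union[str, os.PathLike]) -> None:
    """Write peaks as 10-column narrowPeak; round-trips through read_narrowpeak."""
    with open(path, "w") as fh:
        for rec in records:
            iv = rec.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{rec.name}\t{rec.score}\t"
                f"{rec.strand}\t{rec.signal_value:g}\t{rec.p_value:g}\t"
                f"{rec.q_value:g}\t{rec.summit}\n"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

GenomeLike = Mapping[str, str]


def open_genome(path: Union[str, os.PathLike]) -> "pyfaidx.Fasta":
    """Open an indexed FASTA (builds the .fai on first use)."""
    import pyfaidx

    return pyfaidx.Fasta(str(path), sequence_always_upper=True)


def chrom_sizes(genome) -> dict:
    """Chromosome lengths for a pyfaidx.Fasta or a plain ``{name: seq}`` dict."""
    if isinstance(genome, Mapping):
        return {name: len(seq) for name, seq in genome.items()}
    return {name: len(genome[name]) for name in genome.keys()}


def fetch_sequence(genome, interval: GenomicInterval) -> str:
    """Fetch the uppercased sequence of ``interval``, padding out-of-range
    positions with ``N``.

    ``genome`` is a pyfaidx.Fasta handle or any mapping of name -> sequence.
    The result always has exactly ``end - start`` characters, so windows that
    run past a chromosome edge stay well defined.
    """
    if isinstance(genome, Mapping):
        if interval.chrom not in genome:
            raise KeyError(f"chromosome {interval.chrom!r} not in genome")
        source = str(genome[interval.chrom])
        size = len(source)
    else:
        if interval.chrom not in genome.keys():
            raise KeyError(f"chromosome {interval.chrom!r} not in genome")
        record = genome[interval.chrom]
        size = len(record)
        source = None

    lo = max(interval.start, 0)
    hi = min(interval.end, size)
    if lo >= hi:
        return "N" * len(interval)
    core = source[lo:hi] if source is not None else str(record[lo:hi])
    left = "N" * (lo - interval.start)
    right = "N" * (interval.end - hi)
    return (left + core.upper() + right)


# ---------------------------------------------------------------------------
# Interval arithmetic used by callers that pad windows
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PaddedInterval:
    """An interval whose start may be negative (edge windows before padding).

    Plain data carrier: GenomicInterval enforces start >= 0, but a 1000-bp
    region centred on a window near position 0 legitimately extends below
    zero and is later N-padded by the encoders.
    """

    chrom: str
    start: int
    end: int

    def __len__(self) -> int:
        return self.end - self.start


def fetch_sequence_padded(genome, region: "PaddedInterval") -> str:
    """fetch_sequence for regions that may start below zero."""
    if region.start >= 0:
        return fetch_sequence(genome, GenomicInterval(region.chrom, region.start, region.end))
    pad = -region.start
    if region.end <= 0:
        return "N" * len(region)
    inner = fetch_sequence(genome, GenomicInterval(region.chrom, 0, region.end))
    return "N" * pad + inner


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------

def write_meme(
    motifs: Sequence,
    path: Union[str, os.PathLike],
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> None:
    """Write kernel motifs (objects with ``kernel_index``, ``pfm``,
    ``n_activations``) in MEME minimal format.

    Every PFM column must be a probability distribution; columns that do not
    sum to 1 within 1e-6 raise ValueError.
    """
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or abs(bg.sum() - 1.0) > 1e-6:
        raise ValueError("background must be 4 frequencies summing to 1")
    for motif in motifs:
        pfm = np.asarray(motif.pfm, dtype=float)
        colsums = pfm.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > 1e-6) or np.any(pfm < 0):
            bad = int(np.argmax(np.abs(colsums - 1.0)))
            raise ValueError(
                f"motif kernel_{motif.kernel_index}: column {bad} sums to "
                f"{colsums[bad]:.6f}, not 1"
            )
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\n")
        fh.write("ALPHABET= ACGT\n\n")
        fh.write("strands: +\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A {:.6f} C {:.6f} G {:.6f} T {:.6f}\n\n".format(*bg))
        for motif in motifs:
            pfm = np.asarray(motif.pfm, dtype=float)
            w = pfm.shape[1]
            nsites = max(int(getattr(motif, "n_activations", 1)), 1)
            fh.write(f"MOTIF kernel_{motif.kernel_index}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {w} nsites= {nsites}\n")
            for col in range(w):
                fh.write(" ".join(f"{pfm[row, col]:.6f}" for row in range(4)) + "\n")
            fh.write("\n")


def read_meme(path: Union[str, os.PathLike]) -> List[np.ndarray]:
    """Read back the letter-probability matrices from a MEME minimal file."""
    pfms: List[np.ndarray] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("letter-probability matrix"):
            w = int(line.split("w=")[1].split()[0])
            rows = []
            for j in range(1, w + 1):
                rows.append([float(tok) for tok in lines[i + j].split()])
            pfms.append(np.asarray(rows, dtype=float).T)  # stored row-per-position
            i += w
        i += 1
    return pfms


# ---------------------------------------------------------------------------
# Variant TSV
# ---------------------------------------------------------------------------

VARIANT_HEADER = ("chrom", "pos", "ref", "alt")


def read_variants(path: Union[str, os.PathLike]) -> List[VariantRecord]:
    """Read a variant TSV with header ``chrom pos ref alt`` (0-based pos)."""
    variants: List[VariantRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(h.strip().lower() for h in header[:4]) != VARIANT_HEADER:
            raise ParseError(f"{path}:1: expected header 'chrom\\tpos\\tref\\talt'")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns")
            try:
                variants.append(
                    VariantRecord(fields[0], int(fields[1]), fields[2].upper(), fields[3].upper())
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return variants


def write_variants(variants: Iterable[VariantRecord], path: Union[str, os.PathLike]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(VARIANT_HEADER) + "\n")
        for v in variants:
            fh.write(f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\n")
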