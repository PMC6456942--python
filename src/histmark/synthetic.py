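"""Self-contained synthetic fixtures with known ground truth.

The generator emits exactly the formats the real pipeline consumes: a small
multi-chromosome FASTA genome, one narrowPeak file per histone mark whose
underlying 200-bp sites carry marker-specific planted sequence motifs, a
DNase narrowPeak track whose fold enrichment is elevated at every true
site, and ref/alt variant pairs that do or do not disrupt a planted motif.
A truth table records every planted locus so downstream labels, metrics,
motif recovery, and variant discrimination can be audited exactly.

Marker loci are disjoint grid-aligned windows separated by gaps, so
one-vs-rest labels are unambiguous; the DNase enrichment is identical at
all sites regardless of marker, making accessibility deliberately
uninformative for distinguishing *among* markers (sequence must carry that
signal). Background sequence is i.i.d. with a configurable GC fraction —
adequate for controlled benchmarks, unrealistic as real genome sequence.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .dataset import DEFAULT_MARKERS, WINDOW_BP
from .formats_io import (
    NUCLEOTIDES,
    GenomicInterval,
    PeakRecord,
    VariantRecord,
    write_narrowpeak,
    write_variants,
)

__all__ = [
    "SyntheticConfig",
    "default_motif_pfms",
    "generate_genome",
    "plant_sites",
    "generate_dnase",
    "generate_variant_pairs",
    "simulate",
]

# One distinct consensus 9-mer per histone mark; chosen to be mutually
# dissimilar under all alignments so planted signals do not collide.
_CONSENSUS = (
    "TGACTCAGC",
    "CACGTGGAT",
    "GGGCGGGAC",
    "CTATAAAAG",
    "AGATAAGCA",
    "CCAATCAGG",
    "ACGTCATTG",
)
_CONSENSUS_PROB = 0.94


def default_motif_pfms(n_markers: int = 7) -> List[np.ndarray]:
    """Information-rich 4 x 9 PFMs (~1.6 bits/column), one per marker."""
    pfms = []
    for consensus in _CONSENSUS[:n_markers]:
        pfm = np.full((4, len(consensus)), (1.0 - _CONSENSUS_PROB) / 3.0)
        for col, base in enumerate(consensus):
            pfm[NUCLEOTIDES.index(base), col] = _CONSENSUS_PROB
        pfms.append(pfm)
    return pfms


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_len_bp: int = 500_000
    n_markers: int = 7
    motif_pfms: Optional[List[np.ndarray]] = None
    sites_per_marker: Union[int, Sequence[int]] = 220
    peak_len_bp: int = 200
    background_gc: float = 0.41
    dnase_fold_at_sites: float = 5.0
    dnase_fold_background: float = 0.0
    motif_insertion_prob: float = 1.0
    site_spacing_windows: int = 3  # grid windows between consecutive usable loci

    def __post_init__(self) -> None:
        if self.peak_len_bp < WINDOW_BP:
            raise ValueError(f"peak_len_bp must be >= {WINDOW_BP}")
        if not (0 <= self.background_gc <= 1):
            raise ValueError("background_gc must be in [0, 1]")
        if not (0 < self.motif_insertion_prob <= 1):
            raise ValueError("motif_insertion_prob must be in (0, 1]")
        if self.motif_pfms is None:
            self.motif_pfms = default_motif_pfms(self.n_markers)
        if len(self.motif_pfms) != self.n_markers:
            raise ValueError("need one motif PFM per marker")
        if isinstance(self.sites_per_marker, int):
            self.sites_per_marker = (self.sites_per_marker,) * self.n_markers
        else:
            self.sites_per_marker = tuple(int(s) for s in self.sites_per_marker)
        if len(self.sites_per_marker) != self.n_markers:
            raise ValueError("need one site count per marker")

    @property
    def markers(self) -> Tuple[str, ...]:
        return DEFAULT_MARKERS[: self.n_markers]

    def chrom_names(self) -> List[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def _rng(config: SyntheticConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, tag])


def generate_genome(config: SyntheticConfig) -> Dict[str, str]:
    """i.i.d. background sequence at the configured GC fraction;
    deterministic for a fixed seed."""
    rng = _rng(config, 1)
    g = config.background_gc
    probs = [(1 - g) / 2, g / 2, g / 2, (1 - g) / 2]
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome = {}
    for chrom in config.chrom_names():
        draw = rng.choice(bases, size=config.chrom_len_bp, p=probs)
        genome[chrom] = draw.tobytes().decode("ascii")
    return genome


def write_fasta(genome: Dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for lo in range(0, len(seq), width):
                fh.write(seq[lo : lo + width] + "\n")


# ---------------------------------------------------------------------------
# Sites with planted motifs
# ---------------------------------------------------------------------------

def _candidate_slots(config: SyntheticConfig) -> List[Tuple[str, int]]:
    """Grid-aligned window starts, spaced and kept clear of chromosome edges
    so 1000-bp regions and distance-matched controls fit around each site."""
    margin_windows = 3
    slots = []
    n_windows = config.chrom_len_bp // WINDOW_BP
    for chrom in config.chrom_names():
        for w in range(margin_windows, n_windows - margin_windows,
                       config.site_spacing_windows):
            slots.append((chrom, w * WINDOW_BP))
    return slots


def plant_sites(
    config: SyntheticConfig, genome: Dict[str, str]
) -> Tuple[Dict[str, str], Dict[str, List[PeakRecord]], pd.DataFrame]:
    """Choose disjoint loci per marker, write motif samples into the
    sequence, and emit per-marker peaks plus a truth table."""
    rng = _rng(config, 2)
    slots = _candidate_slots(config)
    needed = sum(config.sites_per_marker)
    if needed > len(slots):
        raise ValueError(
            f"not enough grid room: need {needed} loci, have {len(slots)} slots "
            f"(increase chrom_len_bp or n_chroms)"
        )
    order = rng.permutation(len(slots))
    chosen = [slots[i] for i in order[:needed]]

    editable = {chrom: bytearray(seq, "ascii") for chrom, seq in genome.items()}
    peaks: Dict[str, List[PeakRecord]] = {m: [] for m in config.markers}
    rows = []
    motif_len = config.motif_pfms[0].shape[1]
    offset = 0
    for m, marker in enumerate(config.markers):
        pfm = np.asarray(config.motif_pfms[m])
        block = chosen[offset : offset + config.sites_per_marker[m]]
        offset += config.sites_per_marker[m]
        for chrom, window_start in block:
            peak_start = window_start - (config.peak_len_bp - WINDOW_BP) // 2
            peak_start = max(peak_start, 0)
            peaks[marker].append(
                PeakRecord(
                    GenomicInterval(chrom, peak_start, peak_start + config.peak_len_bp),
                    signal_value=1.0,
                )
            )
            motif_start, motif_seq = -1, ""
            if rng.random() < config.motif_insertion_prob:
                motif_start = window_start + (WINDOW_BP - motif_len) // 2
                sampled = [
                    NUCLEOTIDES[rng.choice(4, p=pfm[:, col] / pfm[:, col].sum())]
                    for col in range(motif_len)
                ]
                motif_seq = "".join(sampled)
                editable[chrom][motif_start : motif_start + motif_len] = motif_seq.encode()
            rows.append(
                {
                    "chrom": chrom,
                    "start": window_start,
                    "end": window_start + WINDOW_BP,
                    "marker": marker,
                    "motif_start": motif_start,
                    "motif_seq": motif_seq,
                }
            )
    edited = {chrom: bytes(buf).decode("ascii") for chrom, buf in editable.items()}
    truth = pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    return edited, peaks, truth


def generate_dnase(config: SyntheticConfig, truth: pd.DataFrame) -> List[PeakRecord]:
    """A DNase peak with the configured fold enrichment over every true
    site; optional uniform background peaks elsewhere."""
    rng = _rng(config, 3)
    peaks = [
        PeakRecord(
            GenomicInterval(row.chrom, int(row.start), int(row.end)),
            signal_value=config.dnase_fold_at_sites,
        )
        for row in truth.itertuples()
    ]
    if config.dnase_fold_background > 0:
        occupied = {(row.chrom, int(row.start)) for row in truth.itertuples()}
        n_windows = config.chrom_len_bp // WINDOW_BP
        for chrom in config.chrom_names():
            for w in range(0, n_windows, config.site_spacing_windows * 4):
                start = w * WINDOW_BP
                if (chrom, start) not in occupied and rng.random() < 0.5:
                    peaks.append(
                        PeakRecord(
                            GenomicInterval(chrom, start, start + WINDOW_BP),
                            signal_value=config.dnase_fold_background,
                        )
                    )
    return peaks


# ---------------------------------------------------------------------------
# Variant pairs
# ---------------------------------------------------------------------------

def generate_variant_pairs(
    config: SyntheticConfig,
    genome: Dict[str, str],
    truth: pd.DataFrame,
    n_pos: int,
    n_neg: int,
    distance_bp: int = 500,
    marker: Optional[str] = None,
) -> Tuple[List[VariantRecord], List[VariantRecord]]:
    """Motif-disrupting positives and distance-matched background controls.

    Positives substitute the central (maximum-information) column of a
    planted motif with that column's least likely base; controls substitute
    a background base about ``distance_bp`` away from a positive. Ref
    alleles always match the (edited) genome. When ``marker`` is given,
    positives disrupt only that marker's sites (the haQTL design targets a
    single mark).
    """
    rng = _rng(config, 4)
    pool = truth if marker is None else truth[truth.marker == marker]
    with_motif = pool[pool.motif_start >= 0].reset_index(drop=True)
    if len(with_motif) < n_pos:
        raise ValueError(
            f"only {len(with_motif)} motif-bearing sites available, need {n_pos}"
        )
    site_windows = [
        (row.chrom, int(row.start), int(row.end)) for row in truth.itertuples()
    ]

    def in_any_site(chrom: str, pos: int) -> bool:
        return any(c == chrom and s <= pos < e for c, s, e in site_windows)

    marker_of = {m: i for i, m in enumerate(config.markers)}
    picks = rng.choice(len(with_motif), size=n_pos, replace=False)
    motif_len = config.motif_pfms[0].shape[1]
    positives: List[VariantRecord] = []
    for idx in picks:
        row = with_motif.iloc[int(idx)]
        pfm = np.asarray(config.motif_pfms[marker_of[row.marker]])
        col = motif_len // 2
        pos = int(row.motif_start) + col
        ref = genome[row.chrom][pos]
        probs = pfm[:, col].copy()
        probs[NUCLEOTIDES.index(ref)] = np.inf  # never pick the ref base
        alt = NUCLEOTIDES[int(np.argmin(probs))]
        positives.append(VariantRecord(row.chrom, pos, ref, alt))

    controls: List[VariantRecord] = []
    for i in range(n_neg):
        anchor = positives[i % len(positives)]
        placed = False
        for offset in _offset_search(distance_bp, tolerance=200, rng=rng):
            pos = anchor.pos + offset
            if pos < 0 or pos >= len(genome[anchor.chrom]):
                continue
            if in_any_site(anchor.chrom, pos):
                continue
            if any(c.chrom == anchor.chrom and c.pos == pos for c in controls):
                continue
            ref = genome[anchor.chrom][pos]
            if ref not in NUCLEOTIDES:
                continue
            others = [b for b in NUCLEOTIDES if b != ref]
            alt = others[int(rng.integers(3))]
            controls.append(VariantRecord(anchor.chrom, pos, ref, alt))
            placed = True
            break
        if not placed:
            raise ValueError(
                f"no background position ~{distance_bp} bp from "
                f"{anchor.chrom}:{anchor.pos}"
            )
    return positives, controls


def _offset_search(distance_bp: int, tolerance: int, rng: np.random.Generator):
    """Offsets +-distance_bp ordered by closeness to the target, direction
    randomized per rank so controls fall on both sides."""
    for delta in range(tolerance + 1):
        signs = (1, -1) if rng.random() < 0.5 else (-1, 1)
        for sign in signs:
            yield sign * (distance_bp + delta)
            if delta:
                yield sign * (distance_bp - delta)


# ---------------------------------------------------------------------------
# Fixture directory
# ---------------------------------------------------------------------------

def simulate(config: SyntheticConfig, outdir) -> Dict[str, str]:
    """Generate the full fixture directory; returns a path map."""
    os.makedirs(outdir, exist_ok=True)
    genome = generate_genome(config)
    genome, peaks, truth = plant_sites(config, genome)
    dnase = generate_dnase(config, truth)

    paths = {"genome": os.path.join(outdir, "genome.fa")}
    write_fasta(genome, paths["genome"])
    for marker in config.markers:
        p = os.path.join(outdir, f"peaks_{marker}.narrowPeak")
        write_narrowpeak(peaks[marker], p)
        paths[f"peaks_{marker}"] = p
    paths["dnase"] = os.path.join(outdir, "dnase.narrowPeak")
    write_narrowpeak(dnase, paths["dnase"])
    paths["truth"] = os.path.join(outdir, "truth.tsv")
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
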