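"""From peak files to labeled, encoded training examples.

The genome is scanned with fixed 200-bp windows on a 200-bp step; a window
overlapping the union of a marker's ChIP-seq peaks by at least 100 bp is a
modification site for that marker. The union of all 7 markers' sites forms
one multi-label table per epigenome: the negatives for any one marker are
the sites of the other markers, never random genome windows. Each 200-bp
site is extended to a 1000-bp region centred on it; sequence is one-hot
encoded (A,C,G,T rows; N -> all-zero column) and chromatin accessibility is
the per-base DNase fold enrichment (0 outside peaks, per-base maximum where
peaks overlap).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Union

import numpy as np

from .formats_io import (
    GenomicInterval,
    PaddedInterval,
    PeakRecord,
    fetch_sequence_padded,
)

__all__ = [
    "DEFAULT_MARKERS",
    "SiteTable",
    "OpennessTrack",
    "EncodedBatch",
    "call_sites",
    "build_site_table",
    "epigenome_passes_filter",
    "center_region",
    "encode_sequence",
    "encode_openness",
    "build_batch",
    "save_dataset",
    "load_dataset",
]

# The 7 histone marks profiled for every epigenome, in canonical column order.
DEFAULT_MARKERS = (
    "H3K4me1",
    "H3K4me3",
    "H3K27me3",
    "H3K36me3",
    "H3K9me3",
    "H3K9ac",
    "H3K27ac",
)

WINDOW_BP = 200
STEP_BP = 200
MIN_OVERLAP_BP = 100
REGION_BP = 1000
SITE_COUNT_THRESHOLD = 50_000

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class SiteTable:
    """Ordered 200-bp windows with an n x 7 binary marker-label matrix."""

    epigenome_id: str
    markers: Sequence[str]
    windows: List[GenomicInterval]
    labels: np.ndarray  # (n, n_markers) uint8

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.shape != (len(self.windows), len(self.markers)):
            raise ValueError("label matrix shape does not match windows x markers")
        if len(self.windows) and not np.all(self.labels.sum(axis=1) >= 1):
            raise ValueError("every window must be a site for at least one marker")

    def __len__(self) -> int:
        return len(self.windows)

    def marker_index(self, marker: str) -> int:
        try:
            return list(self.markers).index(marker)
        except ValueError:
            raise KeyError(f"unknown marker {marker!r}") from None

    def site_counts(self) -> Dict[str, int]:
        sums = self.labels.sum(axis=0)
        return {m: int(sums[i]) for i, m in enumerate(self.markers)}


@dataclass
class OpennessTrack:
    """One epigenome's DNase-seq peaks, with dense per-chromosome caching."""

    peaks: List[PeakRecord]
    _dense: Dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def dense_scores(self, chrom: str, size: int) -> np.ndarray:
        """Per-base openness for ``chrom`` (fold enrichment, max over peaks)."""
        cached = self._dense.get(chrom)
        if cached is not None and len(cached) >= size:
            return cached
        scores = np.zeros(size, dtype=np.float32)
        for peak in self.peaks:
            iv = peak.interval
            if iv.chrom != chrom:
                continue
            lo, hi = max(iv.start, 0), min(iv.end, size)
            if lo < hi:
                seg = scores[lo:hi]
                np.maximum(seg, np.float32(peak.signal_value), out=seg)
        self._dense[chrom] = scores
        return scores


@dataclass
class EncodedBatch:
    """One-hot sequence, openness signal, and labels for n regions."""

    seq: np.ndarray  # (n, 4, L) float32 in {0,1}
    openness: np.ndarray  # (n, 1, L) float32 >= 0
    labels: np.ndarray  # (n, n_markers) float32 in {0,1}

    def __len__(self) -> int:
        return self.seq.shape[0]


# ---------------------------------------------------------------------------
# Site calling
# ---------------------------------------------------------------------------

def call_sites(
    peaks: Sequence[PeakRecord],
    chrom_sizes: Mapping[str, int],
    window_bp: int = WINDOW_BP,
    step_bp: int = STEP_BP,
    min_overlap_bp: int = MIN_OVERLAP_BP,
) -> List[GenomicInterval]:
    """Scan fixed windows over each chromosome and call those overlapping the
    peak union by at least ``min_overlap_bp`` bases.

    Windows are anchored at multiples of ``step_bp`` from coordinate 0. The
    overlap is counted against the *union* of the peaks, so two abutting
    half-window peaks jointly call a window.
    """
    if window_bp <= 0 or step_bp <= 0:
        raise ValueError("window_bp and step_bp must be positive")
    if min_overlap_bp > window_bp:
        raise ValueError(
            f"min_overlap_bp ({min_overlap_bp}) cannot exceed window_bp ({window_bp})"
        )
    if window_bp != step_bp:
        # Non-tiling grids need per-window counting; the tiling fast path
        # below assumes step == window.
        return _call_sites_general(peaks, chrom_sizes, window_bp, step_bp, min_overlap_bp)

    by_chrom: Dict[str, List[PeakRecord]] = {}
    for peak in peaks:
        chrom = peak.interval.chrom
        if chrom not in chrom_sizes:
            raise KeyError(f"peak chromosome {chrom!r} absent from chrom_sizes")
        by_chrom.setdefault(chrom, []).append(peak)

    called: List[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        size = chrom_sizes[chrom]
        n_windows = (size + window_bp - 1) // window_bp
        padded = n_windows * window_bp
        delta = np.zeros(padded + 1, dtype=np.int32)
        for peak in by_chrom[chrom]:
            lo = max(peak.interval.start, 0)
            hi = min(peak.interval.end, size)
            if lo < hi:
                delta[lo] += 1
                delta[hi] -= 1
        covered = (np.cumsum(delta[:-1]) > 0).astype(np.int32)
        per_window = covered.reshape(n_windows, window_bp).sum(axis=1)
        for idx in np.nonzero(per_window >= min_overlap_bp)[0]:
            start = int(idx) * window_bp
            called.append(GenomicInterval(chrom, start, start + window_bp))
    return called


def _call_sites_general(peaks, chrom_sizes, window_bp, step_bp, min_overlap_bp):
    by_chrom: Dict[str, List[PeakRecord]] = {}
    for peak in peaks:
        chrom = peak.interval.chrom
        if chrom not in chrom_sizes:
            raise KeyError(f"peak chromosome {chrom!r} absent from chrom_sizes")
        by_chrom.setdefault(chrom, []).append(peak)
    called: List[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        size = chrom_sizes[chrom]
        delta = np.zeros(size + 1, dtype=np.int32)
        for peak in by_chrom[chrom]:
            lo, hi = max(peak.interval.start, 0), min(peak.interval.end, size)
            if lo < hi:
                delta[lo] += 1
                delta[hi] -= 1
        covered = np.cumsum(delta[:-1]) > 0
        cum = np.concatenate([[0], np.cumsum(covered)])
        start = 0
        while start < size:
            end = min(start + window_bp, size)
            if cum[end] - cum[start] >= min_overlap_bp:
                called.append(GenomicInterval(chrom, start, start + window_bp))
            start += step_bp
    return called


def build_site_table(
    per_marker_sites: Mapping[str, Sequence[GenomicInterval]],
    markers: Sequence[str] = DEFAULT_MARKERS,
    epigenome_id: str = "synthetic",
) -> SiteTable:
    """Union the per-marker site lists into one multi-label table.

    ``labels[i, m] = 1`` iff window i is a site for marker m; every row has at
    least one positive label by construction.
    """
    markers = list(markers)
    for key in per_marker_sites:
        if key not in markers:
            raise KeyError(f"marker {key!r} is not in the marker list {markers}")
    window_set = sorted(
        {w for sites in per_marker_sites.values() for w in sites},
        key=lambda iv: (iv.chrom, iv.start),
    )
    index = {w: i for i, w in enumerate(window_set)}
    labels = np.zeros((len(window_set), len(markers)), dtype=np.uint8)
    for m, marker in enumerate(markers):
        for w in per_marker_sites.get(marker, ()):
            labels[index[w], m] = 1
    return SiteTable(epigenome_id, markers, window_set, labels)


def epigenome_passes_filter(
    site_counts: Mapping[str, int],
    threshold: int = SITE_COUNT_THRESHOLD,
    markers: Sequence[str] = DEFAULT_MARKERS,
) -> bool:
    """True iff every marker has at least ``threshold`` modification sites.

    Epigenomes with fewer than 50,000 sites for any marker are excluded from
    training by default.
    """
    missing = [m for m in markers if m not in site_counts]
    if missing:
        raise KeyError(f"site counts missing for markers: {missing}")
    return all(site_counts[m] >= threshold for m in markers)


# ---------------------------------------------------------------------------
# Region extension and encoding
# ---------------------------------------------------------------------------

def center_region(window: GenomicInterval, region_bp: int = REGION_BP) -> PaddedInterval:
    """Extend a window symmetrically to ``region_bp`` while keeping its
    midpoint; the result may run below 0 or past the chromosome end (the
    encoders pad such positions)."""
    width = len(window)
    if width > region_bp:
        raise ValueError(f"window ({width} bp) longer than region ({region_bp} bp)")
    if (region_bp - width) % 2:
        raise ValueError(
            f"region_bp - window length must be even, got {region_bp} - {width}"
        )
    pad = (region_bp - width) // 2
    return PaddedInterval(window.chrom, window.start - pad, window.end + pad)


def encode_sequence(seq: str) -> np.ndarray:
    """One-hot encode a nucleotide string as a 4 x L binary matrix.

    Row order A, C, G, T. ``N`` yields an all-zero column; any other symbol
    is an error.
    """
    seq = seq.upper()
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.zeros((4, len(seq)), dtype=np.float32)
    for base, row in _BASE_INDEX.items():
        out[row, codes == ord(base)] = 1.0
    known = out.sum(axis=0) > 0
    unknown = ~known & (codes != ord("N"))
    if np.any(unknown):
        pos = int(np.argmax(unknown))
        raise ValueError(f"invalid nucleotide {seq[pos]!r} at position {pos}")
    return out


def encode_openness(
    track: OpennessTrack,
    region: Union[GenomicInterval, PaddedInterval],
    chrom_size: Optional[int] = None,
    log1p: bool = False,
) -> np.ndarray:
    """Per-base openness scores over ``region``.

    A position inside a DNase peak takes that peak's fold enrichment (the
    maximum where peaks overlap); positions outside all peaks — including
    padded positions beyond chromosome bounds — score 0.
    """
    L = region.end - region.start
    if L <= 0:
        raise ValueError("region must have positive length")
    if chrom_size is None:
        chrom_size = max(
            (p.interval.end for p in track.peaks if p.interval.chrom == region.chrom),
            default=0,
        )
    dense = track.dense_scores(region.chrom, chrom_size)
    out = np.zeros(L, dtype=np.float32)
    lo = max(region.start, 0)
    hi = min(region.end, len(dense))
    if lo < hi:
        out[lo - region.start : hi - region.start] = dense[lo:hi]
    if log1p:
        np.log1p(out, out=out)
    return out


def build_batch(
    genome,
    track: OpennessTrack,
    site_table: SiteTable,
    row_indices: Optional[Sequence[int]] = None,
    region_bp: int = REGION_BP,
    log1p_openness: bool = False,
) -> EncodedBatch:
    """Encode the requested site-table rows into network-ready arrays."""
    from .formats_io import chrom_sizes as _chrom_sizes

    if row_indices is None:
        row_indices = range(len(site_table))
    sizes = _chrom_sizes(genome)
    n = len(row_indices)
    seq = np.zeros((n, 4, region_bp), dtype=np.float32)
    openness = np.zeros((n, 1, region_bp), dtype=np.float32)
    labels = np.zeros((n, len(site_table.markers)), dtype=np.float32)
    for out_row, idx in enumerate(row_indices):
        window = site_table.windows[idx]
        region = center_region(window, region_bp)
        seq[out_row] = encode_sequence(fetch_sequence_padded(genome, region))
        openness[out_row, 0] = encode_openness(
            track, region, chrom_size=sizes[window.chrom], log1p=log1p_openness
        )
        labels[out_row] = site_table.labels[idx]
    return EncodedBatch(seq, openness, labels)


# ---------------------------------------------------------------------------
# On-disk dataset directory
# ---------------------------------------------------------------------------

def save_dataset(
    dirpath: Union[str, os.PathLike],
    site_table: SiteTable,
    batch: EncodedBatch,
    manifest_extra: Optional[dict] = None,
) -> None:
    """Persist a site table (BED-like TSV with label columns), the encoded
    arrays (compressed npz shard), and a manifest."""
    os.makedirs(dirpath, exist_ok=True)
    tsv = os.path.join(dirpath, "sites.tsv")
    with open(tsv, "w") as fh:
        fh.write("chrom\tstart\tend\t" + "\t".join(site_table.markers) + "\n")
        for window, row in zip(site_table.windows, site_table.labels):
            fh.write(
                f"{window.chrom}\t{window.start}\t{window.end}\t"
                + "\t".join(str(int(v)) for v in row)
                + "\n"
            )
    np.savez_compressed(
        os.path.join(dirpath, "encoded.npz"),
        seq=batch.seq.astype(np.int8),
        openness=batch.openness,
        labels=batch.labels.astype(np.int8),
    )
    manifest = {
        "epigenome_id": site_table.epigenome_id,
        "markers": list(site_table.markers),
        "n_sites": len(site_table),
        "region_bp": int(batch.seq.shape[2]),
    }
    manifest.update(manifest_extra or {})
    with open(os.path.join(dirpath, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)


def load_dataset(dirpath: Union[str, os.PathLike]):
    """Load a dataset directory saved by :func:`save_dataset`."""
    with open(os.path.join(dirpath, "manifest.json")) as fh:
        manifest = json.load(fh)
    windows: List[GenomicInterval] = []
    rows: List[List[int]] = []
    with open(os.path.join(dirpath, "sites.tsv")) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        markers = header[3:]
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            windows.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
            rows.append([int(v) for v in fields[3:]])
    table = SiteTable(manifest["epigenome_id"], markers, windows, np.asarray(rows, dtype=np.uint8))
    with np.load(os.path.join(dirpath, "encoded.npz")) as data:
        batch = EncodedBatch(
            seq=data["seq"].astype(np.float32),
            openness=data["openness"].astype(np.float32),
            labels=data["labels"].astype(np.float32),
        )
    return table, batch, manifest
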