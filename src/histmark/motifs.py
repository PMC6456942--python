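"""Position frequency matrices from first-layer convolutional kernels.

A kernel's activation on a sequence window is the elementwise product-sum of
its 4 x 9 weight matrix with the window's one-hot encoding. The extreme
activation value (EAV) is the maximum activation over all windows; windows
activating at >= alpha * EAV (alpha = 0.9) are "activated regions", and
averaging their one-hot matrices yields the kernel's PFM, exportable in
MEME format for downstream motif comparison (e.g. TomTom against JASPAR).

The EAV reference can be taken per scanned sequence or over the whole
scanned sample (``MotifConfig.eav_scope``). The default is the global
scope: under the per-sequence rule every sequence with a positive EAV
contributes at least its own best window, so kernels whose motif occurs in
only a fraction of the sample have their PFM diluted by the other
sequences' best background windows. The per-sequence reading remains
available for comparison.

Sequences (or samples) whose EAV is not positive contribute nothing: with
a non-positive maximum the threshold rule would admit arbitrarily weak
windows, and only positively activating evidence should shape a motif.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .network import ModelHandle

__all__ = [
    "MotifConfig",
    "KernelMotif",
    "kernel_eav",
    "extract_pwm",
    "extract_all_motifs",
    "motif_similarity",
    "information_content",
    "write_motif_summary",
]


@dataclass
class MotifConfig:
    alpha: float = 0.9
    kernel_len: int = 9
    min_activations: int = 10
    eav_scope: str = "global"  # "global": alpha * max EAV over all scanned
    # sequences; "sequence": alpha * EAV of each sequence separately

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.min_activations < 1:
            raise ValueError("min_activations must be >= 1")
        if self.eav_scope not in ("global", "sequence"):
            raise ValueError("eav_scope must be 'global' or 'sequence'")


@dataclass
class KernelMotif:
    kernel_index: int
    pfm: np.ndarray  # (4, kernel_len), column-stochastic
    n_activations: int
    n_sequences_scanned: int


def _window_activations(kernel: np.ndarray, seq_onehot: np.ndarray) -> np.ndarray:
    """Activation of every length-k window of one sequence (valid positions
    only, no padding)."""
    k = kernel.shape[1]
    L = seq_onehot.shape[1]
    if L < k:
        raise ValueError(f"sequence length {L} shorter than kernel length {k}")
    s0, s1 = seq_onehot.strides
    windows = np.lib.stride_tricks.as_strided(
        seq_onehot, shape=(4, k, L - k + 1), strides=(s0, s1, s1), writeable=False
    )
    return np.tensordot(kernel, windows, axes=([0, 1], [0, 1]))


def kernel_eav(kernel_weights: np.ndarray, seq_onehot: np.ndarray) -> float:
    """Extreme activation value: the maximum kernel activation over all
    windows of one one-hot encoded sequence."""
    return float(_window_activations(np.asarray(kernel_weights), seq_onehot).max())


def extract_pwm(
    kernel_weights: np.ndarray,
    sequences: Sequence[np.ndarray],
    config: MotifConfig = MotifConfig(),
) -> Optional[np.ndarray]:
    """Average the one-hot content of all activated windows into a PFM.

    Every window with activation >= alpha * EAV is collected, where the EAV
    reference is the sample-wide maximum (default) or each sequence's own
    maximum (``eav_scope="sequence"``). Windows containing an ambiguous
    base (all-zero column) are skipped so PFM columns stay stochastic.
    Returns None (skip-signal) when fewer than ``min_activations`` windows
    activate across all sequences.
    """
    if len(sequences) == 0:
        raise ValueError("extract_pwm needs at least one sequence")
    pfm, _count = _scan_kernel(np.asarray(kernel_weights, dtype=np.float32), sequences, config)
    return pfm


def _scan_kernel(kernel, sequences, config):
    k = kernel.shape[1]
    total = np.zeros((4, k), dtype=np.float64)
    count = 0
    if config.eav_scope == "global":
        global_eav = max(
            (_window_activations(kernel, seq).max() for seq in sequences),
            default=0.0,
        )
        if global_eav <= 0:
            return None, 0
    for seq in sequences:
        acts = _window_activations(kernel, seq)
        eav = global_eav if config.eav_scope == "global" else acts.max()
        if eav <= 0:
            continue
        for pos in np.nonzero(acts >= config.alpha * eav)[0]:
            window = seq[:, pos : pos + k]
            if np.any(window.sum(axis=0) < 0.5):  # contains N
                continue
            total += window
            count += 1
    if count < config.min_activations:
        return None, count
    return (total / count).astype(np.float64), count


def extract_all_motifs(
    model: ModelHandle,
    sequences: Sequence[np.ndarray],
    config: MotifConfig = MotifConfig(),
) -> List[KernelMotif]:
    """Apply the activation rule to every first-layer DNA kernel over a
    sample of input sequences; kernels below the activation floor are
    skipped. Deterministic for a fixed sample."""
    if len(sequences) == 0:
        raise ValueError("extract_all_motifs needs at least one sequence")
    kernels = model.first_layer_kernels()
    motifs: List[KernelMotif] = []
    for idx, kernel in enumerate(kernels):
        pfm, count = _scan_kernel(kernel.astype(np.float32), sequences, config)
        if pfm is None:
            continue
        motifs.append(KernelMotif(idx, pfm, count, len(sequences)))
    return motifs


def motif_similarity(pfm_a: np.ndarray, pfm_b: np.ndarray) -> float:
    """Pearson correlation of the flattened matrices."""
    a = np.asarray(pfm_a, dtype=float).ravel()
    b = np.asarray(pfm_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("matrices must have the same shape")
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def information_content(pfm: np.ndarray) -> float:
    """Total information content in bits (2 - entropy, summed over columns)."""
    p = np.clip(np.asarray(pfm, dtype=float), 1e-9, 1.0)
    return float(np.sum(2.0 + (p * np.log2(p)).sum(axis=0)))


def write_motif_summary(path, motifs: Sequence[KernelMotif]) -> None:
    with open(path, "w") as fh:
        fh.write("kernel_index\tn_activations\tn_sequences\tinformation_content\n")
        for m in motifs:
            fh.write(
                f"{m.kernel_index}\t{m.n_activations}\t{m.n_sequences_scanned}\t"
                f"{information_content(m.pfm):.4f}\n"
            )
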