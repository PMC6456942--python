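"""In-silico variant scoring and distance-matched control sets.

For a SNP, the 1000-bp sequence centred at its position is scored twice —
once with the reference allele and once with the alternate — and the
functional implication score is the absolute probability shift
``delta_p = |p_alt - p_ref|`` for the marker of interest. The openness
signal is identical for both alleles: a single-base substitution does not
edit the accessibility measurement.

Control sets mirror the haQTL analysis: for each positive SNP a control SNP
is matched at a target genomic distance (500/1000/1500/2000/2500 bp), and
score distributions are compared with a one-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .dataset import EncodedBatch, OpennessTrack, encode_openness, encode_sequence
from .evaluation import wilcoxon_rank_sum_one_sided
from .formats_io import (
    NUCLEOTIDES,
    PaddedInterval,
    VariantRecord,
    chrom_sizes,
    fetch_sequence_padded,
)
from .network import ModelHandle

__all__ = [
    "VariantScore",
    "RefMismatchError",
    "score_variant",
    "score_variants",
    "build_control_set",
    "compare_scores",
]

REGION_BP = 1000


class RefMismatchError(ValueError):
    """The genome base at the variant position does not equal the stated ref."""


@dataclass
class VariantScore:
    variant: VariantRecord
    marker: str
    p_ref: float
    p_alt: float

    @property
    def delta_p(self) -> float:
        return abs(self.p_alt - self.p_ref)


Scorer = Union[ModelHandle, Sequence[ModelHandle]]


def _ensemble_predict(scorer: Scorer, batch: EncodedBatch) -> np.ndarray:
    models = [scorer] if isinstance(scorer, ModelHandle) else list(scorer)
    if not models:
        raise ValueError("scorer must contain at least one model")
    preds = [
        m.forward(
            seq=batch.seq if m.dna_branch is not None else None,
            openness=batch.openness if m.dnase_branch is not None else None,
        )
        for m in models
    ]
    return np.mean(preds, axis=0)


def score_variant(
    scorer: Scorer,
    genome,
    track: OpennessTrack,
    variant: VariantRecord,
    marker: str,
    markers: Optional[Sequence[str]] = None,
    region_bp: int = REGION_BP,
) -> VariantScore:
    """Score one SNP for one marker with a model or fold-model ensemble.

    Builds the ``region_bp`` window centred at the SNP, checks that the
    genome base matches the reference allele, and predicts probabilities for
    the unmodified and the single-base-substituted sequence over the same
    openness vector.
    """
    from .dataset import DEFAULT_MARKERS

    markers = list(markers) if markers is not None else list(DEFAULT_MARKERS)
    m = markers.index(marker)
    half = region_bp // 2
    region = PaddedInterval(variant.chrom, variant.pos - half, variant.pos - half + region_bp)
    ref_seq = fetch_sequence_padded(genome, region)
    center = variant.pos - region.start
    genome_base = ref_seq[center]
    if genome_base != variant.ref:
        raise RefMismatchError(
            f"{variant.chrom}:{variant.pos}: genome base is {genome_base!r}, "
            f"variant says ref={variant.ref!r}"
        )
    alt_seq = ref_seq[:center] + variant.alt + ref_seq[center + 1 :]
    sizes = chrom_sizes(genome)
    openness = encode_openness(track, region, chrom_size=sizes[variant.chrom])
    seq_pair = np.stack([encode_sequence(ref_seq), encode_sequence(alt_seq)])
    open_pair = np.repeat(openness[None, None, :], 2, axis=0)
    labels = np.zeros((2, len(markers)), dtype=np.float32)
    probs = _ensemble_predict(scorer, EncodedBatch(seq_pair, open_pair, labels))
    return VariantScore(variant, marker, float(probs[0, m]), float(probs[1, m]))


def score_variants(
    scorer: Scorer,
    genome,
    track: OpennessTrack,
    variants: Sequence[VariantRecord],
    marker: str,
    markers: Optional[Sequence[str]] = None,
) -> List[VariantScore]:
    return [score_variant(scorer, genome, track, v, marker, markers) for v in variants]


def build_control_set(
    positives: Sequence[VariantRecord],
    candidates: Sequence[VariantRecord],
    target_distance_bp: int,
    tolerance_bp: int = 250,
) -> Tuple[List[VariantRecord], List[VariantRecord]]:
    """Match each positive SNP to an unused candidate SNP on the same
    chromosome whose distance is closest to ``target_distance_bp`` and
    within ``tolerance_bp`` of it.

    Matching is without replacement, in positive order. Positives with no
    admissible candidate are dropped so the two returned lists stay
    equal-sized and aligned.
    """
    if not candidates:
        raise ValueError("candidate list must be non-empty")
    pos_keys = {(p.chrom, p.pos) for p in positives}
    used = [False] * len(candidates)
    kept: List[VariantRecord] = []
    controls: List[VariantRecord] = []
    for positive in positives:
        best_idx, best_gap = -1, None
        for i, cand in enumerate(candidates):
            if used[i] or cand.chrom != positive.chrom:
                continue
            if (cand.chrom, cand.pos) in pos_keys:
                continue
            gap = abs(abs(cand.pos - positive.pos) - target_distance_bp)
            if gap > tolerance_bp:
                continue
            if best_gap is None or gap < best_gap:
                best_idx, best_gap = i, gap
        if best_idx >= 0:
            used[best_idx] = True
            kept.append(positive)
            controls.append(candidates[best_idx])
    return kept, controls


def compare_scores(
    pos_scores: Sequence[float], neg_scores: Sequence[float]
) -> Tuple[float, Dict[str, float]]:
    """One-sided Wilcoxon rank-sum test of "positive scores greater", plus
    the two medians."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    p_value = wilcoxon_rank_sum_one_sided(pos, neg)
    summary = {
        "median_pos": float(np.median(pos)),
        "median_neg": float(np.median(neg)),
        "n_pos": int(pos.size),
        "n_neg": int(neg.size),
    }
    return p_value, summary


def write_scores_tsv(path, scores: Sequence[VariantScore]) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tmarker\tp_ref\tp_alt\tdelta_p\n")
        for s in scores:
            v = s.variant
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{s.marker}\t"
                f"{s.p_ref:.6f}\t{s.p_alt:.6f}\t{s.delta_p:.6f}\n"
            )
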