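"""Evaluation with one-vs-rest semantics, exact tests, collective scoring.

For each histone mark the positive class is the windows carrying that mark
and the negative class is the *other markers'* sites that lack it — a far
more stringent negative set than random genome draws, since modification
sites of different marks share properties like GC content. auROC is the
rank (concordance) statistic with ties counted one half; auPRC is average
precision. Paired method comparisons across epigenomes use the one-sided
exact binomial sign test; variant-score comparisons use the one-sided
Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .dataset import SiteTable

__all__ = [
    "MetricResult",
    "UndefinedMetricError",
    "one_vs_rest_labels",
    "auroc",
    "auprc",
    "evaluate_predictions",
    "paired_sign_test",
    "wilcoxon_rank_sum_one_sided",
    "collective_predict",
    "write_metrics_tsv",
]


class UndefinedMetricError(ValueError):
    """Raised when a metric's class requirements are not met."""


@dataclass
class MetricResult:
    marker: str
    auroc: float
    auprc: float
    n_pos: int
    n_neg: int


def one_vs_rest_labels(site_table: SiteTable, marker: str) -> np.ndarray:
    """Binary labels over all table rows for one marker: rows carrying the
    marker are positive, all other rows (sites of other markers) negative."""
    m = site_table.marker_index(marker)
    return site_table.labels[:, m].astype(np.int8)


def _check_binary(labels: np.ndarray) -> Tuple[int, int]:
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    return n_pos, n_neg


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Probability that a random positive outranks a random negative, with
    ties counted one half (equivalently, area under the ROC curve)."""
    labels = np.asarray(labels)
    n_pos, n_neg = _check_binary(labels)
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError(
            f"auROC needs both classes (n_pos={n_pos}, n_neg={n_neg})"
        )
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def auprc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the precision-recall curve in the average-precision form
    (precision summed at each recall step)."""
    labels = np.asarray(labels)
    n_pos, _ = _check_binary(labels)
    if n_pos == 0:
        raise UndefinedMetricError("auPRC needs at least one positive")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def evaluate_predictions(
    site_table: SiteTable, predictions: np.ndarray
) -> List[MetricResult]:
    """Per-marker one-vs-rest auROC/auPRC for a full prediction matrix.

    Markers whose one-vs-rest split is degenerate (no positives or no
    negatives in the table) are reported with NaN metrics.
    """
    predictions = np.asarray(predictions, dtype=float)
    if predictions.shape != (len(site_table), len(site_table.markers)):
        raise ValueError("prediction matrix shape must be n_sites x n_markers")
    results = []
    for m, marker in enumerate(site_table.markers):
        labels = one_vs_rest_labels(site_table, marker)
        n_pos, n_neg = _check_binary(labels)
        if n_pos == 0 or n_neg == 0:
            results.append(MetricResult(marker, float("nan"), float("nan"), n_pos, n_neg))
            continue
        results.append(
            MetricResult(
                marker,
                auroc(predictions[:, m], labels),
                auprc(predictions[:, m], labels),
                n_pos,
                n_neg,
            )
        )
    return results


# ---------------------------------------------------------------------------
# Statistical tests
# ---------------------------------------------------------------------------

def paired_sign_test(wins: int, n: int) -> float:
    """One-sided exact binomial (sign) test: P(X >= wins), X ~ Bin(n, 1/2).

    ``wins`` counts the paired comparisons the first method won; ties must
    be removed beforehand (with n reduced).
    """
    if n <= 0:
        raise UndefinedMetricError("sign test undefined after removing all ties (n=0)")
    if not (0 <= wins <= n):
        raise ValueError(f"wins must be in [0, {n}], got {wins}")
    return float(stats.binomtest(wins, n, 0.5, alternative="greater").pvalue)


def wilcoxon_rank_sum_one_sided(
    x: Sequence[float], y: Sequence[float]
) -> float:
    """One-sided Wilcoxon rank-sum tail probability for the alternative
    "x stochastically greater than y".

    Exact enumeration for small tie-free samples (min size <= 10 and
    combined size <= 20); tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    small = min(x.size, y.size) <= 10 and combined.size <= 20
    method = "exact" if (small and not has_ties) else "asymptotic"
    kwargs = {} if method == "exact" else {"use_continuity": False}
    return float(
        stats.mannwhitneyu(x, y, alternative="greater", method=method, **kwargs).pvalue
    )


# ---------------------------------------------------------------------------
# Cross-epigenome collective scoring
# ---------------------------------------------------------------------------

def collective_predict(models_per_epigenome: Sequence[Sequence], batch) -> np.ndarray:
    """Predict a novel epigenome by averaging over known epigenomes.

    Each known epigenome contributes its CV-fold models; the per-epigenome
    score is the mean over those fold models, and the final score is the
    unweighted mean over epigenomes. The batch carries the region sequences
    together with the *novel* epigenome's openness track.
    """
    if len(models_per_epigenome) == 0:
        raise ValueError("collective_predict needs at least one known epigenome")
    epigenome_means = []
    for fold_models in models_per_epigenome:
        fold_models = list(fold_models)
        if not fold_models:
            raise ValueError("each epigenome must contribute at least one model")
        preds = [
            m.forward(
                seq=batch.seq if m.dna_branch is not None else None,
                openness=batch.openness if m.dnase_branch is not None else None,
            )
            for m in fold_models
        ]
        epigenome_means.append(np.mean(preds, axis=0))
    return np.mean(epigenome_means, axis=0)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def write_metrics_tsv(path, epigenome_id: str, results: Sequence[MetricResult]) -> None:
    with open(path, "w") as fh:
        fh.write("epigenome\tmarker\tn_pos\tn_neg\tauROC\tauPRC\n")
        for r in results:
            fh.write(
                f"{epigenome_id}\t{r.marker}\t{r.n_pos}\t{r.n_neg}\t"
                f"{r.auroc:.6f}\t{r.auprc:.6f}\n"
            )


def read_metrics_tsv(path) -> Dict[str, Dict[str, float]]:
    """marker -> {auROC, auPRC, ...} from a metrics TSV."""
    out: Dict[str, Dict[str, float]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            fields = dict(zip(header, line.rstrip("\n").split("\t")))
            out[fields["marker"]] = {
                "auROC": float(fields["auROC"]),
                "auPRC": float(fields["auPRC"]),
            }
    return out


def compare_metric_tables(
    a: Dict[str, Dict[str, float]],
    b: Dict[str, Dict[str, float]],
    metric: str = "auROC",
) -> Tuple[int, int, float]:
    """Win count of table a over table b on shared markers and the one-sided
    sign-test tail probability (ties dropped)."""
    shared = sorted(set(a) & set(b))
    wins = sum(1 for m in shared if a[m][metric] > b[m][metric])
    losses = sum(1 for m in shared if a[m][metric] < b[m][metric])
    n = wins + losses
    return wins, n, paired_sign_test(wins, n) if n else float("nan")
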