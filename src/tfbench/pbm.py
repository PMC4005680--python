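"""PBM probe handling, positive-probe calling and prediction-quality metrics.

A protein-binding microarray reports one normalized median intensity per
probe; only the 36 bp of unique probe sequence carry signal.  Probes bound
by the TF ("positives") are called by a robust outlier rule: intensity
greater than the median by more than 4 * (MAD / 0.6745), where MAD is the raw
median absolute deviation and 0.6745 is the median absolute deviation of the
standard normal, so MAD/0.6745 estimates sigma under normality.

Model quality against a probe table is summarised by three statistics:
Spearman rank correlation on the positive probes, sensitivity at 1% false
positive rate, and the ROC AUC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

from .pwm import PWMSet, pwm_set_score, reverse_complement
from .selex import KmerTable

#: Median of |Z| for Z ~ N(0,1), as conventionally printed.
MAD_NORMAL_CONSTANT = 0.6745


def standard_normal_mad() -> float:
    """Median absolute deviation of the standard normal: Phi^-1(0.75) ~= 0.6745.

    For a symmetric zero-median distribution the MAD is the 75th percentile,
    so the constant is the normal upper quartile.
    """
    return float(stats.norm.ppf(0.75))


@dataclass
class ProbeTable:
    """PBM probe sequences with their normalized median intensities."""

    sequences: list[str]
    intensities: np.ndarray
    experiment_id: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if len(self.sequences) != len(self.intensities):
            raise ValueError("sequences and intensities differ in length")
        if not np.isfinite(self.intensities).all():
            raise ValueError("intensities must be finite")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"probes of mixed lengths {sorted(lengths)}")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def probe_length(self) -> int:
        return len(self.sequences[0])


@dataclass
class PositiveCallResult:
    """Outcome of the MAD-based positive-probe rule."""

    threshold: float
    median: float
    mad: float
    labels: np.ndarray  # boolean per probe

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())


@dataclass
class EvalMetrics:
    """The three prediction-quality statistics for one experiment.

    ``spearman_on_positives`` is None when fewer than 3 positive probes exist
    (the correlation is then undefined, reported as missing rather than 0).
    """

    spearman_on_positives: float | None
    sens_at_1pct_fpr: float
    auc: float


def call_positive_probes(
    intensities: Sequence[float] | np.ndarray, multiplier: float = 4.0
) -> PositiveCallResult:
    """Label probes whose intensity exceeds median + multiplier*(MAD/0.6745).

    MAD here is the raw median absolute deviation from the median; the 0.6745
    divisor enters only in the threshold.  The inequality is strict, so
    boundary equality is negative.
    """
    x = np.asarray(intensities, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 probes to call positives")
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    threshold = med + multiplier * (mad / MAD_NORMAL_CONSTANT)
    return PositiveCallResult(
        threshold=threshold, median=med, mad=mad, labels=x > threshold
    )


def _check_two_classes(labels: np.ndarray) -> tuple[np.ndarray, int, int]:
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative")
    return labels, n_pos, n_neg


def auc_score(labels: Iterable[bool], scores: Iterable[float]) -> float:
    """Rank-statistic ROC AUC: P(random positive outscores random negative).

    Ties count one half, making this identical to the trapezoidal area under
    the step ROC curve.
    """
    scores = np.asarray(list(scores), dtype=float)
    labels, n_pos, n_neg = _check_two_classes(np.asarray(list(labels)))
    ranks = stats.rankdata(scores)  # average ranks handle ties as 1/2
    pos_rank_sum = ranks[labels].sum()
    return float((pos_rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def sensitivity_at_fpr(
    labels: Iterable[bool], scores: Iterable[float], fpr: float = 0.01
) -> float:
    """True-positive rate at the most permissive threshold with FPR <= fpr.

    The ROC is treated as a step function (no interpolation), and probes with
    tied scores enter or leave the predicted-positive set together.
    """
    if not 0 < fpr < 1:
        raise ValueError("fpr must be in (0, 1)")
    scores = np.asarray(list(scores), dtype=float)
    labels, _, _ = _check_two_classes(np.asarray(list(labels)))
    fprs, tprs, _ = roc_curve(labels, scores, drop_intermediate=False)
    return float(tprs[fprs <= fpr].max())


def spearman_on_positives(
    measured: Iterable[float],
    predicted: Iterable[float],
    labels: Iterable[bool],
) -> float | None:
    """Spearman rank correlation restricted to the positive probes.

    Returns None (undefined) with fewer than 3 positives.  Ties receive
    average ranks, as in the standard statistic.
    """
    measured = np.asarray(list(measured), dtype=float)
    predicted = np.asarray(list(predicted), dtype=float)
    labels = np.asarray(list(labels), dtype=bool)
    if labels.sum() < 3:
        return None
    m, p = measured[labels], predicted[labels]
    if np.ptp(m) == 0 or np.ptp(p) == 0:  # constant input: undefined
        return None
    return float(stats.spearmanr(m, p).statistic)


def evaluate_pbm(
    table: ProbeTable,
    model: PWMSet,
    strand_mode: str = "both",
    fpr: float = 0.01,
    mad_multiplier: float = 4.0,
) -> EvalMetrics:
    """Score every probe with the PWM set and compute the three metrics.

    The predicted intensity of a probe is the max-over-models sum occupancy
    score of its unique 36-base sequence; positives come from the MAD rule on
    the measured intensities.
    """
    predicted = np.array(
        [pwm_set_score(model, s, strand_mode) for s in table.sequences]
    )
    call = call_positive_probes(table.intensities, multiplier=mad_multiplier)
    return EvalMetrics(
        spearman_on_positives=spearman_on_positives(
            table.intensities, predicted, call.labels
        ),
        sens_at_1pct_fpr=sensitivity_at_fpr(call.labels, predicted, fpr),
        auc=auc_score(call.labels, predicted),
    )


def kmer_intensity_scores(
    table: ProbeTable, k: int = 8, statistic: str = "mean"
) -> KmerTable:
    """Average (or median) probe intensity for every k-mer present on the array.

    A probe "contains" a k-mer if the word occurs in its sequence on either
    strand of the double-stranded probe; a probe contributes at most one
    intensity observation per k-mer regardless of how many times the word
    occurs.  k-mers carried by no probe are absent from the table.
    """
    if statistic not in ("mean", "median"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if k > table.probe_length:
        raise ValueError(f"k={k} exceeds probe length {table.probe_length}")
    observations: dict[str, list[float]] = {}
    for seq, intensity in zip(table.sequences, table.intensities):
        kmers = {seq[j : j + k] for j in range(len(seq) - k + 1)}
        rc = reverse_complement(seq)
        kmers.update(rc[j : j + k] for j in range(len(rc) - k + 1))
        for w in kmers:
            observations.setdefault(w, []).append(float(intensity))
    agg = np.mean if statistic == "mean" else np.median
    kind = "intensity_mean" if statistic == "mean" else "intensity_median"
    return KmerTable(
        {w: float(agg(v)) for w, v in observations.items()}, k=k, score_kind=kind
    )
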