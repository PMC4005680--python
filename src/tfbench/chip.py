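"""ChIP-seq evaluation sets and in-vivo AUC for PWM models.

Positives are the strongest peaks (smallest p-value): the 250 bp around each
peak center.  Negatives are 250 bp flanks 300 bp downstream of the same
centers — nearby genomic sequence shares GC content and k-mer statistics
with the peak, so the contrast isolates motif content.  All coordinates are
0-based half-open (BED convention): "250 bp around the center" is
[c-125, c+125) and the downstream flank is [c+300, c+550).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .pbm import auc_score
from .pwm import PWMSet, pwm_set_score

logger = logging.getLogger(__name__)

POS_HALFWIDTH = 125
NEG_OFFSET = 300
NEG_LENGTH = 250


@dataclass(frozen=True)
class PeakRecord:
    """One ChIP-seq peak: half-open interval plus its reported p-value."""

    chrom: str
    start: int
    end: int
    pvalue: float
    id: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak {self.id!r}: start must be < end")
        if self.pvalue < 0:
            raise ValueError(f"peak {self.id!r}: p-value must be >= 0")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class LabeledSequenceSet:
    """Paired positive/negative 250-bp sequences with their genomic provenance."""

    positives: list[str]
    negatives: list[str]
    provenance: list[tuple[str, int, int]] = field(default_factory=list)
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if len(self.positives) != len(self.negatives):
            raise ValueError("positives and negatives must be paired")


def select_top_peaks(peaks: Sequence[PeakRecord], n: int = 500) -> list[PeakRecord]:
    """The n peaks with the smallest p-value; ties break by (chrom, start).

    If fewer than n peaks exist, all are returned with a warning.
    """
    if not peaks:
        raise ValueError("empty peak list")
    if len(peaks) < n:
        logger.warning("only %d peaks available, requested %d", len(peaks), n)
    ordered = sorted(peaks, key=lambda p: (p.pvalue, p.chrom, p.start))
    return ordered[:n]


def build_pos_neg_sets(
    peaks: Sequence[PeakRecord],
    genome: Mapping[str, str],
    flank_mode: str = "downstream",
    pos_halfwidth: int = POS_HALFWIDTH,
    neg_offset: int = NEG_OFFSET,
    neg_length: int = NEG_LENGTH,
) -> LabeledSequenceSet:
    """Extract positive windows around peak centers and flanking negatives.

    For a peak with center c the positive is [c-125, c+125); the negative is
    [c+300, c+550) downstream or [c-550, c-300) upstream on the reference
    plus strand (peaks are unstranded).  A peak whose positive or negative
    window runs off the contig is dropped entirely — both members — so the
    classes stay paired; the drop count is recorded.
    """
    if flank_mode not in ("downstream", "upstream"):
        raise ValueError(f"unknown flank_mode {flank_mode!r}")
    positives, negatives, provenance = [], [], []
    n_dropped = 0
    for peak in peaks:
        if peak.chrom not in genome:
            raise KeyError(f"chromosome {peak.chrom!r} missing from genome")
        contig = genome[peak.chrom]
        c = peak.center
        pos_ivl = (c - pos_halfwidth, c + pos_halfwidth)
        if flank_mode == "downstream":
            neg_ivl = (c + neg_offset, c + neg_offset + neg_length)
        else:
            neg_ivl = (c - neg_offset - neg_length, c - neg_offset)
        if min(pos_ivl[0], neg_ivl[0]) < 0 or max(pos_ivl[1], neg_ivl[1]) > len(contig):
            n_dropped += 1
            continue
        positives.append(contig[pos_ivl[0] : pos_ivl[1]].upper())
        negatives.append(contig[neg_ivl[0] : neg_ivl[1]].upper())
        provenance.append((peak.chrom, pos_ivl[0], pos_ivl[1]))
    if n_dropped:
        logger.info("dropped %d off-contig peak pairs", n_dropped)
    return LabeledSequenceSet(
        positives=positives,
        negatives=negatives,
        provenance=provenance,
        n_dropped=n_dropped,
    )


def evaluate_chip(
    seq_set: LabeledSequenceSet,
    model: PWMSet,
    strand_mode: str = "both",
    allow_n: bool = True,
) -> float:
    """AUC for separating peak sequences from their flanks with a PWM set.

    Every sequence gets the max-over-models occupancy score.  Genomic
    sequence may contain N, scored leniently at 0.25 by default.
    """
    if not seq_set.positives or not seq_set.negatives:
        raise ValueError("both classes must be non-empty")
    scores = [
        pwm_set_score(model, s, strand_mode, allow_n=allow_n)
        for s in seq_set.positives + seq_set.negatives
    ]
    labels = [True] * len(seq_set.positives) + [False] * len(seq_set.negatives)
    return auc_score(labels, scores)


def mean_auc(aucs: Sequence[float]) -> float:
    """Average AUC over the experiments available for one TF."""
    if not aucs:
        raise ValueError("no AUC values to average")
    return float(np.mean(aucs))
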