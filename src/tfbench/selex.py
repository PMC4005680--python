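"""Per-cycle oligo and k-mer statistics for HT-SELEX experiments.

An HT-SELEX experiment is an ordered series of sequencing samples ("cycles",
cycle 0 being the unselected initial pool).  Each cycle is summarised as a
table of oligo counts; k-mer statistics derived from it — occurrence
frequencies, between-cycle frequency ratios, nucleotide composition — are the
model-independent currency used to compare SELEX against PBM measurements and
to audit technology biases.

k-mer counting is read-strand only by default: both the oligo synthesis and
the sequencing chemistry are strand-specific, so A/T (and C/G) frequencies
need not be equal and collapsing strands would mask exactly the biases the
audit looks for.  A ``both_strands`` switch exists for sensitivity analysis.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

from .pwm import reverse_complement

SCORE_KINDS = ("intensity_mean", "intensity_median", "frequency", "ratio", "affinity")


@dataclass
class CycleTable:
    """Oligo counts for one SELEX cycle."""

    counts: dict[str, int]
    cycle_index: int = 0

    def __post_init__(self) -> None:
        if self.counts:
            lengths = {len(o) for o in self.counts}
            if len(lengths) != 1:
                raise ValueError(f"oligos of mixed lengths {sorted(lengths)}")
            if any(c <= 0 for c in self.counts.values()):
                raise ValueError("oligo counts must be positive")

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    @property
    def oligo_length(self) -> int:
        if not self.counts:
            raise ValueError("empty cycle has no oligo length")
        return len(next(iter(self.counts)))


@dataclass
class SelexExperiment:
    """Ordered cycles (0 = initial pool) plus the experiment's seed k-mers."""

    tf_name: str
    oligo_length: int
    cycles: list[CycleTable] = field(default_factory=list)
    seeds: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, cyc in enumerate(self.cycles):
            if cyc.counts and cyc.oligo_length != self.oligo_length:
                raise ValueError(
                    f"cycle {i} oligo length {cyc.oligo_length} != {self.oligo_length}"
                )

    @property
    def n_cycles(self) -> int:
        """Index of the last cycle (cycles run 0..n_cycles)."""
        return len(self.cycles) - 1

    @property
    def last_cycle(self) -> CycleTable:
        return self.cycles[-1]


@dataclass
class KmerTable:
    """Mapping k-mer -> score.

    ``score_kind`` records the statistic: mean/median probe intensity (PBM),
    or occurrence frequency / between-cycle frequency ratio (SELEX).
    """

    scores: dict[str, float]
    k: int
    score_kind: str

    def __post_init__(self) -> None:
        if self.score_kind not in SCORE_KINDS:
            raise ValueError(f"unknown score_kind {self.score_kind!r}")
        if any(len(w) != self.k for w in self.scores):
            raise ValueError("all keys must have length k")
        if self.score_kind == "frequency" and self.scores:
            total = sum(self.scores.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(f"frequency table sums to {total}, not 1")

    def __len__(self) -> int:
        return len(self.scores)

    def __getitem__(self, kmer: str) -> float:
        return self.scores[kmer]

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.scores


def count_kmers(
    cycle: CycleTable, k: int, both_strands: bool = False
) -> Counter[str]:
    """Occurrences of every k-mer across all reads, weighted by read count."""
    if not cycle.counts:
        raise ValueError("empty cycle")
    if k > cycle.oligo_length:
        raise ValueError(f"k={k} exceeds oligo length {cycle.oligo_length}")
    occ: Counter[str] = Counter()
    for oligo, n in cycle.counts.items():
        for j in range(len(oligo) - k + 1):
            occ[oligo[j : j + k]] += n
        if both_strands:
            rc = reverse_complement(oligo)
            for j in range(len(rc) - k + 1):
                occ[rc[j : j + k]] += n
    return occ


def kmer_frequency_table(
    cycle: CycleTable, k: int = 8, both_strands: bool = False
) -> KmerTable:
    """k-mer occurrence frequencies in one cycle.

    The denominator is the total number of k-mer windows, so the table is a
    probability vector; with a fixed oligo length this differs from a
    per-read denominator only by a constant and induces the same ranking.
    """
    occ = count_kmers(cycle, k, both_strands)
    total = sum(occ.values())
    return KmerTable({w: c / total for w, c in occ.items()}, k=k, score_kind="frequency")


def kmer_ratio_table(
    cycle_i: CycleTable,
    cycle_prev: CycleTable,
    k: int = 8,
    both_strands: bool = False,
) -> KmerTable:
    """Between-cycle enrichment: frequency in cycle i over frequency in cycle i-1.

    k-mers absent from the earlier cycle have an undefined (infinite) ratio
    and are excluded: a finite score is required downstream, and an infinity
    would dominate any top-k selection spuriously.
    """
    freq_i = kmer_frequency_table(cycle_i, k, both_strands)
    freq_prev = kmer_frequency_table(cycle_prev, k, both_strands)
    ratios = {
        w: s / freq_prev.scores[w]
        for w, s in freq_i.scores.items()
        if w in freq_prev.scores
    }
    return KmerTable(ratios, k=k, score_kind="ratio")


def top_k_kmers(table: KmerTable, n: int = 100) -> list[str]:
    """The n highest-scoring k-mers, descending; score ties break lexicographically."""
    if not table.scores:
        raise ValueError("empty k-mer table")
    ordered = sorted(table.scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return [w for w, _ in ordered[:n]]


def nucleotide_composition(cycle: CycleTable) -> dict[str, float]:
    """Per-base fraction over all read positions (read strand only)."""
    if not cycle.counts:
        raise ValueError("empty cycle")
    base_counts: Counter[str] = Counter()
    for oligo, n in cycle.counts.items():
        for b, c in Counter(oligo).items():
            base_counts[b] += c * n
    total = sum(base_counts.values())
    return {b: base_counts.get(b, 0) / total for b in "ACGT"}


def oligo_enrichment_ratio(
    oligo: str, last: CycleTable, prev: CycleTable
) -> float:
    """Oligo frequency in the last cycle over its frequency in the previous one.

    Returns ``math.inf`` (not an exception) when the oligo was unseen in the
    previous cycle — the signature of a contaminant surging from below the
    sampling floor.
    """
    f_last = last.counts.get(oligo, 0) / last.total_reads
    f_prev = prev.counts.get(oligo, 0) / prev.total_reads
    if f_prev == 0:
        return math.inf if f_last > 0 else 0.0
    return f_last / f_prev
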