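"""Model-independent PBM vs HT-SELEX comparison.

Each technology ranks 8-mers — PBM by average probe intensity, SELEX by
per-cycle frequency or between-cycle ratio.  The comparison takes the top
100 8-mers under one technology and computes the Pearson correlation of
their scores across both, over the grid of (cycle, source of the top list,
SELEX score kind).  Also here: approximate matching of top 8-mers (allowing
mismatches and an alignment offset), the per-cycle top-8-mer trajectory, and
the rule calling an experiment's model set a failure when its AUC trails the
PBM-model average by a margin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

from .bias import KmerCategory, classify_kmer
from .pwm import reverse_complement
from .selex import (
    KmerTable,
    SelexExperiment,
    kmer_frequency_table,
    kmer_ratio_table,
    top_k_kmers,
)


class CorrelationResult(NamedTuple):
    """Correlation over a top-n key set; value is None when < 3 shared keys."""

    value: float | None
    n_used: int
    n_dropped: int


def top_k_correlation(
    table_a: KmerTable,
    table_b: KmerTable,
    n: int = 100,
    method: str = "pearson",
) -> CorrelationResult:
    """Correlate the top-n k-mers of ``table_a`` across the two tables.

    Keys from a's top-n missing from b are dropped (their count is reported)
    rather than imputed zero, which would be arbitrary on a ratio scale.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    top = top_k_kmers(table_a, n)
    shared = [w for w in top if w in table_b.scores]
    n_dropped = len(top) - len(shared)
    if len(shared) < 3:
        return CorrelationResult(None, len(shared), n_dropped)
    a = np.array([table_a.scores[w] for w in shared])
    b = np.array([table_b.scores[w] for w in shared])
    if np.ptp(a) == 0 or np.ptp(b) == 0:  # constant input: correlation undefined
        return CorrelationResult(None, len(shared), n_dropped)
    corr = stats.pearsonr(a, b) if method == "pearson" else stats.spearmanr(a, b)
    return CorrelationResult(float(corr.statistic), len(shared), n_dropped)


@dataclass
class GridEntry:
    cycle: int
    source: str  # "pbm_top" | "selex_top"
    selex_score: str  # "frequency" | "ratio"
    pearson: float
    n_used: int
    n_dropped: int


@dataclass
class ComparisonGridResult:
    entries: list[GridEntry]
    best: GridEntry


_SOURCE_ORDER = {"pbm_top": 0, "selex_top": 1}
_SCORE_ORDER = {"frequency": 0, "ratio": 1}


def run_comparison_grid(
    selex: SelexExperiment,
    pbm_kmers: KmerTable,
    n: int = 100,
    k: int = 8,
    include_cycle0: bool = True,
    max_cycle: int | None = None,
) -> ComparisonGridResult:
    """Pearson correlation for every (cycle, top-list source, SELEX score) cell.

    Frequency scores exist for every cycle (optionally including the
    unselected cycle 0); ratio scores need a predecessor and start at cycle 1.
    The ``best`` cell maximises the correlation; ties resolve to the lowest
    cycle, then pbm_top before selex_top, then frequency before ratio.
    ``max_cycle`` lets a caller drop sparsely covered late cycles from the
    comparison without recomputing.
    """
    if selex.n_cycles < 1:
        raise ValueError("need at least cycles 0 and 1 for a comparison grid")
    last = selex.n_cycles if max_cycle is None else min(max_cycle, selex.n_cycles)
    entries: list[GridEntry] = []
    freq_tables = {c: kmer_frequency_table(selex.cycles[c], k) for c in range(last + 1)}
    for cycle in range(0 if include_cycle0 else 1, last + 1):
        tables = {"frequency": freq_tables[cycle]}
        if cycle >= 1:
            tables["ratio"] = kmer_ratio_table(
                selex.cycles[cycle], selex.cycles[cycle - 1], k
            )
        for score_kind, selex_table in tables.items():
            for source, (ta, tb) in {
                "pbm_top": (pbm_kmers, selex_table),
                "selex_top": (selex_table, pbm_kmers),
            }.items():
                res = top_k_correlation(ta, tb, n=n)
                if res.value is None:
                    continue
                entries.append(
                    GridEntry(
                        cycle=cycle,
                        source=source,
                        selex_score=score_kind,
                        pearson=res.value,
                        n_used=res.n_used,
                        n_dropped=res.n_dropped,
                    )
                )
    if not entries:
        raise ValueError("no grid cell had enough shared k-mers to correlate")
    best = min(
        entries,
        key=lambda e: (
            -e.pearson,
            e.cycle,
            _SOURCE_ORDER[e.source],
            _SCORE_ORDER[e.selex_score],
        ),
    )
    return ComparisonGridResult(entries=entries, best=best)


def _mismatches_at_shift(a: str, b: str, shift: int) -> int:
    """Mismatch count inside the overlap when b is shifted right by `shift`."""
    k = len(a)
    if shift >= 0:
        pairs = zip(a[shift:], b[: k - shift])
    else:
        pairs = zip(a[: k + shift], b[-shift:])
    return sum(x != y for x, y in pairs)


def kmer_match(
    a: str,
    b: str,
    max_mismatch: int = 2,
    max_offset: int = 2,
    check_rc: bool = True,
) -> bool:
    """Approximate identity of two equal-length k-mers.

    True iff some alignment shift in [-max_offset, +max_offset] leaves at
    most ``max_mismatch`` mismatches inside the overlapping positions
    (overlap length k - |shift|; positions without a counterpart are
    ignored).  With ``check_rc``, b's reverse complement is tried as well,
    treating a word and its complement as the same double-stranded site.
    """
    if len(a) != len(b):
        raise ValueError("k-mers must have equal length")
    candidates = [b, reverse_complement(b)] if check_rc else [b]
    for cand in candidates:
        for shift in range(-max_offset, max_offset + 1):
            if _mismatches_at_shift(a, cand, shift) <= max_mismatch:
                return True
    return False


@dataclass
class TrajectoryRecord:
    cycle: int
    top_kmer: str
    matched: bool
    category: KmerCategory


def top_kmer_trajectory(
    selex: SelexExperiment,
    pbm_kmers: KmerTable,
    k: int = 8,
    max_mismatch: int = 2,
    max_offset: int = 2,
    check_rc: bool = True,
) -> list[TrajectoryRecord]:
    """Per cycle: the most frequent k-mer, whether it matches the top PBM
    k-mer (approximate match), and its bias category."""
    pbm_top = top_k_kmers(pbm_kmers, 1)[0]
    records = []
    for cycle_table in selex.cycles:
        freq = kmer_frequency_table(cycle_table, k)
        top = top_k_kmers(freq, 1)[0]
        records.append(
            TrajectoryRecord(
                cycle=cycle_table.cycle_index,
                top_kmer=top,
                matched=kmer_match(top, pbm_top, max_mismatch, max_offset, check_rc),
                category=classify_kmer(top),
            )
        )
    return records


def failure_call(
    auc_selex: float, auc_pbm: list[float], margin: float = 0.1
) -> bool:
    """Call a SELEX model set a failure when its AUC trails the mean PBM AUC
    by at least ``margin`` (boundary inclusive)."""
    if not auc_pbm:
        raise ValueError("auc_pbm must be non-empty")
    vals = list(auc_pbm) + [auc_selex]
    if any(not 0 <= v <= 1 for v in vals):
        raise ValueError("AUC values must lie in [0, 1]")
    # tolerance keeps the "at least" boundary inclusive under float rounding
    return float(np.mean(auc_pbm)) - auc_selex >= margin - 1e-9
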