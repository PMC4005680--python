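"""Systematic-bias audits for HT-SELEX data.

Two bias families are covered.  k-mer level: poly(A) and poly(C) 8-mers
(at least 7 A's or 7 C's) are overabundant and, for poly(C), magnified from
cycle to cycle, while palindromic 8-mers (words equal to their own reverse
complement) are underrepresented and less magnified; these are quantified by
per-category frequency summaries, a Monte-Carlo uniform-null test and a
two-sample Kolmogorov-Smirnov test on between-cycle rates of change.
Oligo level: "false oligos" — reads among the most frequent in the last
cycle that contain no binding seed even allowing one mismatch — are detected
and characterised by composition skew and by surging from absence in the
previous cycle.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import stats

from .pwm import reverse_complement
from .selex import CycleTable, KmerTable, oligo_enrichment_ratio


class KmerCategory(Enum):
    POLY_A = "poly_a"
    POLY_C = "poly_c"
    PALINDROME = "palindrome"
    OTHER = "other"


def classify_kmer(w: str) -> KmerCategory:
    """Assign a k-mer to poly(A), poly(C), palindrome or other.

    poly(A)/poly(C): at least k-1 of the k bases are A (resp. C).  Palindrome:
    the word equals its own reverse complement.  The poly checks run first;
    for 8-mers the categories are provably exclusive (a palindrome pairs each
    A with a T and each C with a G, so it can hold at most k/2 of any base),
    but the precedence is fixed so other k behave deterministically.
    """
    w = w.upper()
    if any(c not in "ACGT" for c in w):
        raise ValueError(f"k-mer {w!r} contains non-ACGT characters")
    poly_threshold = len(w) - 1
    counts = Counter(w)
    if counts.get("A", 0) >= poly_threshold:
        return KmerCategory.POLY_A
    if counts.get("C", 0) >= poly_threshold:
        return KmerCategory.POLY_C
    if w == reverse_complement(w):
        return KmerCategory.PALINDROME
    return KmerCategory.OTHER


@dataclass
class CategorySummary:
    category: KmerCategory
    count: int
    median: float
    mean: float
    scores: np.ndarray


def category_density(freq_table: KmerTable) -> dict[KmerCategory, CategorySummary]:
    """Group a frequency table's scores by k-mer category and summarise each group."""
    groups: dict[KmerCategory, list[float]] = {c: [] for c in KmerCategory}
    for w, s in freq_table.scores.items():
        groups[classify_kmer(w)].append(s)
    out = {}
    for cat, vals in groups.items():
        arr = np.asarray(sorted(vals), dtype=float)
        out[cat] = CategorySummary(
            category=cat,
            count=arr.size,
            median=float(np.median(arr)) if arr.size else math.nan,
            mean=float(arr.mean()) if arr.size else math.nan,
            scores=arr,
        )
    return out


def uniform_null_pvalue(
    observed_median_freq: float,
    category_size: int,
    total_kmer_draws: int,
    n_mc: int = 10_000,
    seed: int = 0,
    k: int = 8,
) -> float:
    """Monte-Carlo p-value for a category median under uniform k-mer sampling.

    Null: ``total_kmer_draws`` k-mers fall uniformly on the 4^k words; the
    test statistic is the median frequency of the category's
    ``category_size`` cells.  Only the joint of those cells plus a remainder
    cell needs simulating (a multinomial margin is itself multinomial).  The
    tail probability uses the add-one estimator (1 + exceedances)/(1 + n_mc),
    so the smallest attainable p is 1/(n_mc + 1).
    """
    if n_mc < 1000:
        raise ValueError("n_mc must be >= 1000 for a stable tail estimate")
    cell_p = 4.0 ** (-k)
    pvec = np.full(category_size + 1, cell_p)
    pvec[-1] = 1.0 - category_size * cell_p
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(total_kmer_draws, pvec, size=n_mc)[:, :-1]
    medians = np.median(draws, axis=1) / total_kmer_draws
    exceed = int((medians >= observed_median_freq).sum())
    return (1 + exceed) / (1 + n_mc)


@dataclass
class KSResult:
    statistic: float
    pvalue: float
    n_palindrome: int
    n_other: int


def ks_rate_change_test(
    freq_c3: KmerTable,
    freq_c4: KmerTable,
    min_keys: int = 10,
    n_perm: int | None = None,
    seed: int = 0,
) -> KSResult | None:
    """K-S test: do palindromes change frequency between cycles like other 8-mers?

    The per-word rate of change is frequency in the later cycle divided by
    frequency in the earlier one, over words present in both.  Palindrome
    rates are compared with the rates of `other`-category words (poly(A) and
    poly(C) are excluded from both groups).  Returns None when either group
    has fewer than ``min_keys`` words.  The p-value is asymptotic unless
    ``n_perm`` requests a permutation p for small samples.
    """
    rates_pal, rates_other = [], []
    for w, f3 in freq_c3.scores.items():
        f4 = freq_c4.scores.get(w)
        if f4 is None:
            continue
        cat = classify_kmer(w)
        if cat is KmerCategory.PALINDROME:
            rates_pal.append(f4 / f3)
        elif cat is KmerCategory.OTHER:
            rates_other.append(f4 / f3)
    if len(rates_pal) < min_keys or len(rates_other) < min_keys:
        return None
    if n_perm is None:
        res = stats.ks_2samp(rates_pal, rates_other, method="asymp")
    else:
        res = stats.ks_2samp(
            rates_pal,
            rates_other,
            method=stats.PermutationMethod(
                n_resamples=n_perm, rng=np.random.default_rng(seed)
            ),
        )
    return KSResult(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        n_palindrome=len(rates_pal),
        n_other=len(rates_other),
    )


def _matches_with_mismatches(window: str, seed_kmer: str, max_mismatch: int) -> bool:
    mm = 0
    for a, b in zip(window, seed_kmer):
        if a != b:
            mm += 1
            if mm > max_mismatch:
                return False
    return True


def oligo_contains_seed(oligo: str, seeds: list[str], max_mismatch: int = 1) -> bool:
    """True iff some window of the oligo, on either strand, matches a seed
    with at most ``max_mismatch`` mismatches."""
    for strand in (oligo, reverse_complement(oligo)):
        for seed_kmer in seeds:
            m = len(seed_kmer)
            if m > len(strand):
                raise ValueError(
                    f"seed {seed_kmer!r} longer than oligo of length {len(strand)}"
                )
            for j in range(len(strand) - m + 1):
                if _matches_with_mismatches(strand[j : j + m], seed_kmer, max_mismatch):
                    return True
    return False


@dataclass
class FalseOligoReport:
    """Partition of the most frequent last-cycle oligos into true and false,
    with the characterisation statistics of each side."""

    top_oligos: list[str]
    false_set: list[str]
    true_set: list[str]
    false_fraction: float
    skewed_fraction_false: float | None = None
    skewed_fraction_true: float | None = None
    absent_prev_fraction_false: float | None = None
    absent_prev_fraction_true: float | None = None
    enrichment_ratios: dict[str, float] = field(default_factory=dict)


def find_false_oligos(
    last: CycleTable,
    seeds: list[str],
    n_top: int = 100,
    max_mismatch: int = 1,
) -> FalseOligoReport:
    """Partition the ``n_top`` most frequent oligos by seed containment.

    An oligo is *true* if it carries any experiment seed (either strand,
    up to ``max_mismatch`` mismatches) and *false* otherwise.  Count ties in
    the top-n selection break lexicographically for reproducibility.
    """
    if not seeds:
        raise ValueError("at least one seed k-mer is required")
    ordered = sorted(last.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    top = [o for o, _ in ordered[:n_top]]
    true_set = [o for o in top if oligo_contains_seed(o, seeds, max_mismatch)]
    false_set = [o for o in top if o not in set(true_set)]
    return FalseOligoReport(
        top_oligos=top,
        false_set=false_set,
        true_set=true_set,
        false_fraction=len(false_set) / len(top) if top else 0.0,
    )


def max_base_fraction(oligo: str) -> float:
    """Fraction of the oligo made of its most common base."""
    return max(Counter(oligo).values()) / len(oligo)


def false_oligo_stats(
    report: FalseOligoReport,
    last: CycleTable,
    prev: CycleTable,
    skew_threshold: float = 0.5,
) -> FalseOligoReport:
    """Fill in the skew / novelty / enrichment statistics of a partition.

    *Skewed*: one nucleotide makes up at least ``skew_threshold`` of the
    oligo.  *Absent-prev*: count zero in the previous cycle.  Per-oligo
    enrichment ratios (last over previous frequency; inf when previously
    unseen) are attached for reporting.
    """

    def _fractions(group: list[str]) -> tuple[float | None, float | None]:
        if not group:
            return None, None
        skewed = sum(max_base_fraction(o) >= skew_threshold for o in group)
        absent = sum(prev.counts.get(o, 0) == 0 for o in group)
        return skewed / len(group), absent / len(group)

    report.skewed_fraction_false, report.absent_prev_fraction_false = _fractions(
        report.false_set
    )
    report.skewed_fraction_true, report.absent_prev_fraction_true = _fractions(
        report.true_set
    )
    report.enrichment_ratios = {
        o: oligo_enrichment_ratio(o, last, prev) for o in report.top_oligos
    }
    return report
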