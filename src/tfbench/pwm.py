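"""Position weight matrices and sum-occupancy scoring.

A PWM models a transcription-factor binding site as independent per-position
base probabilities.  The predicted binding intensity of a sequence is its
*sum occupancy score*: the sum, over every length-k window, of the product of
the matrix probabilities for the bases in that window.  Because probes, SELEX
oligos and genomic peaks are double-stranded, the default scoring mode adds
the same quantity computed on the reverse complement; ``strand_mode="given"``
scores the literal input strand only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# code 4 = N; used only when lenient N handling is enabled
_ENCODE_LUT = np.full(256, -1, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _ENCODE_LUT[ord(_b)] = _i
_ENCODE_LUT[ord("N")] = 4


class DegenerateColumnError(ValueError):
    """A count-matrix column is all zero and no pseudocount was given."""


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of a sequence over {A,C,G,T,N}."""
    seq = seq.upper()
    if any(c not in "ACGTN" for c in seq):
        bad = sorted({c for c in seq if c not in "ACGTN"})
        raise ValueError(f"invalid characters in sequence: {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


def encode_sequence(seq: str, allow_n: bool = False) -> np.ndarray:
    """Encode a DNA string as int8 codes A=0, C=1, G=2, T=3 (N=4 if allowed)."""
    codes = _ENCODE_LUT[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        bad = sorted({seq[i] for i in np.nonzero(codes < 0)[0]})
        raise ValueError(f"invalid characters in sequence: {bad}")
    if not allow_n and (codes == 4).any():
        raise ValueError(
            "sequence contains N; pass allow_n=True to score N positions at 0.25"
        )
    return codes


@dataclass(frozen=True)
class PWM:
    """A base-probability matrix: 4 rows in A,C,G,T order, one column per position.

    Parameters
    ----------
    probs
        Array of shape (4, k); every column must sum to 1 (within 1e-9) and
        all entries must lie in [0, 1].
    name
        Identifier carried through readers/writers and reports.
    source
        Technology the matrix was learned from: ``pbm``, ``selex`` or
        ``synthetic``.
    """

    probs: np.ndarray
    name: str = ""
    source: str = "synthetic"

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.ndim != 2 or probs.shape[0] != 4 or probs.shape[1] < 1:
            raise ValueError(f"PWM must be 4 x k with k >= 1, got {probs.shape}")
        if (probs < -1e-12).any() or (probs > 1 + 1e-12).any():
            raise ValueError("PWM entries must lie in [0, 1]")
        colsums = probs.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValueError(f"PWM columns must sum to 1, got {colsums}")
        if self.source not in ("pbm", "selex", "synthetic"):
            raise ValueError(f"unknown source {self.source!r}")
        object.__setattr__(self, "probs", probs)

    @property
    def k(self) -> int:
        return self.probs.shape[1]

    def __len__(self) -> int:
        return self.k

    def reverse_complement(self) -> "PWM":
        """PWM scoring the reverse-complement strand (rows and columns flipped)."""
        return PWM(self.probs[::-1, ::-1].copy(), name=self.name, source=self.source)


@dataclass
class PWMSet:
    """An ordered collection of PWMs reported for one TF.

    A sequence is scored by the best member (max over models): when a
    technology reports several matrices for a TF, the highest occupancy score
    among them is the predicted binding intensity.
    """

    pwms: list[PWM] = field(default_factory=list)
    tf_name: str = ""

    def __post_init__(self) -> None:
        if not self.pwms:
            raise ValueError("PWMSet must contain at least one PWM")

    def __iter__(self):
        return iter(self.pwms)

    def __len__(self) -> int:
        return len(self.pwms)


def normalize_pwm(
    counts: np.ndarray | Sequence[Sequence[float]],
    pseudocount: float = 0.0,
    name: str = "",
    source: str = "synthetic",
) -> PWM:
    """Turn a 4 x k non-negative count matrix into a probability PWM.

    Each column becomes ``(counts + pseudocount) / sum``.  A column that is
    all zero with ``pseudocount == 0`` has no defined distribution and raises
    :class:`DegenerateColumnError`.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 4:
        raise ValueError(f"count matrix must be 4 x k, got {counts.shape}")
    if (counts < 0).any():
        raise ValueError("count matrix entries must be non-negative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    adjusted = counts + pseudocount
    colsums = adjusted.sum(axis=0)
    if (colsums <= 0).any():
        bad = int(np.nonzero(colsums <= 0)[0][0])
        raise DegenerateColumnError(
            f"column {bad} is all zero and pseudocount is 0"
        )
    return PWM(adjusted / colsums, name=name, source=source)


def _window_products(probs: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Per-window occupancy products for one encoded sequence (codes may hold 4=N)."""
    k = probs.shape[1]
    # row 4 scores N as the uniform 0.25
    lut = np.vstack([probs, np.full((1, k), 0.25)])
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    return lut[windows, np.arange(k)].prod(axis=1)


def occupancy_score(
    pwm: PWM,
    seq: str,
    strand_mode: str = "both",
    allow_n: bool = False,
) -> float:
    """Sum occupancy score of ``seq`` under ``pwm``.

    Sum over all windows j of prod_i Theta_i(seq[j+i]).  With
    ``strand_mode="both"`` the same sum computed on the reverse complement is
    added, treating the input as double-stranded DNA.  N bases are rejected
    unless ``allow_n`` is set, in which case each N contributes the uniform
    probability 0.25 to its windows.
    """
    if strand_mode not in ("given", "both"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    seq = seq.upper()
    if len(seq) < pwm.k:
        raise ValueError(f"sequence of length {len(seq)} shorter than PWM (k={pwm.k})")
    codes = encode_sequence(seq, allow_n=allow_n)
    score = float(_window_products(pwm.probs, codes).sum())
    if strand_mode == "both":
        rc_codes = encode_sequence(reverse_complement(seq), allow_n=allow_n)
        score += float(_window_products(pwm.probs, rc_codes).sum())
    return score


def occupancy_scores_batch(
    pwm: PWM,
    encoded: np.ndarray,
    strand_mode: str = "both",
) -> np.ndarray:
    """Occupancy scores for many equal-length encoded sequences at once.

    ``encoded`` is an (n, L) int array of base codes 0..3.  Used by the
    simulators, where per-oligo Python loops would dominate the run time.
    """
    if encoded.ndim != 2:
        raise ValueError("encoded must be 2-D (n sequences x L bases)")
    k = pwm.k
    if encoded.shape[1] < k:
        raise ValueError("sequences shorter than PWM")
    windows = np.lib.stride_tricks.sliding_window_view(encoded, k, axis=1)
    scores = pwm.probs[windows, np.arange(k)].prod(axis=2).sum(axis=1)
    if strand_mode == "both":
        rc = 3 - encoded[:, ::-1]
        windows = np.lib.stride_tricks.sliding_window_view(rc, k, axis=1)
        scores = scores + pwm.probs[windows, np.arange(k)].prod(axis=2).sum(axis=1)
    return scores


def pwm_set_score(
    pwm_set: PWMSet,
    seq: str,
    strand_mode: str = "both",
    allow_n: bool = False,
) -> float:
    """Max over member PWMs of the occupancy score; the multi-model prediction.

    Members longer than the sequence are skipped; if none fits, an error is
    raised.
    """
    fitting = [p for p in pwm_set.pwms if p.k <= len(seq)]
    if not fitting:
        raise ValueError(
            f"no PWM in set {pwm_set.tf_name!r} fits a sequence of length {len(seq)}"
        )
    return max(occupancy_score(p, seq, strand_mode, allow_n) for p in fitting)


def information_content(pwm: PWM) -> np.ndarray:
    """Per-column information content in bits: 2 - H(column), with 0*log(0)=0."""
    p = pwm.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    return 2.0 + plogp.sum(axis=0)


def trim_pwm(pwm: PWM, n: int) -> PWM:
    """Trim to the contiguous window of ``n`` columns with maximal total IC.

    Matrices already at most ``n`` columns are returned unchanged.  Ties go to
    the leftmost window so that trimming is deterministic.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if pwm.k <= n:
        return pwm
    ic = information_content(pwm)
    window_ic = np.convolve(ic, np.ones(n), mode="valid")
    # argmax returns the first (leftmost) maximum
    start = int(np.argmax(np.round(window_ic, 12)))
    return PWM(pwm.probs[:, start : start + n].copy(), name=pwm.name, source=pwm.source)


def consensus_kmer(pwm: PWM) -> str:
    """Per-column argmax base; ties resolved in A<C<G<T order."""
    return "".join(BASES[int(i)] for i in np.argmax(pwm.probs, axis=0))


def sample_site(pwm: PWM, rng: np.random.Generator) -> str:
    """Draw one binding-site sequence from the PWM's per-column distributions."""
    cols = [rng.choice(4, p=pwm.probs[:, j]) for j in range(pwm.k)]
    return "".join(BASES[int(c)] for c in cols)
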