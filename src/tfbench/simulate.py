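"""Seeded generators for synthetic PBM, HT-SELEX and ChIP data.

All three generators share one hidden ground-truth PWM, so that every
evaluation stage — occupancy scoring, metric computation, cross-technology
correlation, bias auditing — can be exercised against data whose answer is
known, with no downloads.

What is emulated, per assay:

* **PBM**: random double-stranded 36-bp probes whose intensity is a baseline
  plus a gain times the probe's occupancy score, under multiplicative
  log-normal noise (microarray noise is classically multiplicative).
* **HT-SELEX**: a finite random oligo pool put through cycles of
  affinity-proportional selection (weight ``(occupancy + floor) ** strength``,
  the floor being non-specific background binding),
  per-base multiplicative amplification bias, optional sequence-independent
  contaminant oligos that amplify geometrically, and finite-depth sequencing
  of each cycle.  The pool itself is resampled at finite size each cycle, so
  sampling drift and overspecification emerge as in the real assay.
* **ChIP**: a random genome with non-overlapping peaks; with probability
  ``plant_prob`` a site sampled from the PWM is written near the peak
  center, and reported peak p-values correlate with planting.

Everything is bit-reproducible given ``(seed, config)``; independent random
streams are derived per generator so changing one knob never perturbs
another stage's draws.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chip import PeakRecord
from .pbm import ProbeTable
from .pwm import (
    BASES,
    PWM,
    consensus_kmer,
    encode_sequence,
    occupancy_scores_batch,
    sample_site,
)
from .selex import CycleTable, KmerTable, SelexExperiment


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for the synthetic generators; defaults give a clean, realistic run.

    The PWM is 8 positions with sharp, margin-separated columns (mean column
    information content about 1.5 bits, typical of strong motifs); the PBM
    arm uses 40000 probes of 36 bp (the coverage of a real all-10-mer array) with moderate log-normal noise; the SELEX
    arm runs 4 cycles on a 100000-molecule pool of 16-bp oligos at 5000
    sequenced reads per cycle (read depth well below the 65536 possible
    8-mers, as in the real assay).  ``selection_strength`` is calibrated so
    the consensus enriches roughly two orders of magnitude per cycle, and
    ``nonspecific_floor`` adds the TF's sequence-independent background
    binding so that unselected oligos survive at a composition-independent
    rate.  Bias knobs (amplification bias, contaminants) are off unless
    switched on.
    """

    seed: int = 0
    # ground-truth PWM
    pwm_length: int = 8
    pwm_concentration: float = 0.1
    # PBM
    n_probes: int = 40_000
    probe_length: int = 36
    intensity_scale: float = 5000.0
    intensity_baseline: float = 100.0
    noise_sigma: float = 0.25
    # SELEX
    n_cycles: int = 4
    pool_size: int = 100_000
    reads_per_cycle: int = 5_000
    oligo_length: int = 16
    selection_strength: float = 0.3
    nonspecific_floor: float = 1e-6
    amp_bias: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    contaminant_oligos: tuple[str, ...] = ()
    contaminant_amplification: float = 8.0
    # ChIP
    n_peaks: int = 500
    plant_prob: float = 1.0
    background_gc: float = 0.5

    def __post_init__(self) -> None:
        for name in (
            "n_probes",
            "probe_length",
            "n_cycles",
            "pool_size",
            "reads_per_cycle",
            "oligo_length",
            "n_peaks",
            "pwm_length",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.plant_prob <= 1:
            raise ValueError("plant_prob must be in [0, 1]")
        if not 0 < self.background_gc < 1:
            raise ValueError("background_gc must be in (0, 1)")
        if any(b <= 0 for b in self.amp_bias):
            raise ValueError("amp_bias weights must be positive")


@dataclass
class GroundTruth:
    """What the generator knows: the PWM, true affinities and planted sites."""

    pwm: PWM
    affinities: dict[str, float] = field(default_factory=dict)
    planted_positions: list[tuple[str, int] | None] = field(default_factory=list)
    contaminants: list[str] = field(default_factory=list)


def _stream(config: SimulationConfig, stream_id: int) -> np.random.Generator:
    """Independent deterministic random stream per generator stage."""
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream_id]))


def _background_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _decode(codes: np.ndarray) -> str:
    return "".join(BASES[c] for c in codes)


def gen_pwm(
    length: int, concentration: float, seed: int, consensus_margin: float = 0.2
) -> PWM:
    """Draw a ground-truth PWM with symmetric-Dirichlet columns.

    ``concentration`` controls column sharpness: as it approaches 0, columns
    approach one-hot (near-deterministic consensus); large values give
    near-uniform columns.  Each column is redrawn until its preferred base
    beats the runner-up by ``consensus_margin`` in probability, so the
    ground-truth consensus is well defined at every position (as it is in
    published matrices for strong motifs); pass 0 to disable.
    """
    if length < 4:
        raise ValueError("PWM length must be >= 4")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    cols = []
    for _ in range(length):
        for _attempt in range(1000):
            col = rng.dirichlet(np.full(4, concentration))
            top2 = np.sort(col)[-2:]
            if top2[1] - top2[0] >= consensus_margin:
                break
        cols.append(col)
    return PWM(np.array(cols).T, name=f"synthetic_pwm_k{length}", source="synthetic")


def gen_pbm_experiment(
    pwm: PWM, config: SimulationConfig
) -> tuple[ProbeTable, GroundTruth]:
    """Random probes with occupancy-driven intensities under log-normal noise.

    intensity = (baseline + scale * occupancy(both strands)) * exp(N(0, sigma^2)).
    With ``noise_sigma=0`` the intensity ranking equals the occupancy ranking
    exactly; with ``intensity_scale=0`` intensities carry no sequence signal.
    """
    rng = _stream(config, 1)
    probs = _background_probs(config.background_gc)
    codes = rng.choice(4, size=(config.n_probes, config.probe_length), p=probs)
    occ = occupancy_scores_batch(pwm, codes, strand_mode="both")
    noise = np.exp(rng.normal(0.0, config.noise_sigma, size=config.n_probes))
    intensities = (config.intensity_baseline + config.intensity_scale * occ) * noise
    sequences = [_decode(row) for row in codes]
    truth = GroundTruth(
        pwm=pwm, affinities=dict(zip(sequences, occ.tolist()))
    )
    return (
        ProbeTable(sequences, intensities, experiment_id="synthetic_pbm"),
        truth,
    )


def _composition_amp_factors(codes: np.ndarray, amp_bias: np.ndarray) -> np.ndarray:
    """Per-oligo amplification factor: product of per-base weights over the oligo."""
    log_w = np.log(amp_bias)
    return np.exp(log_w[codes].sum(axis=1))


def gen_selex_experiment(
    pwm: PWM, config: SimulationConfig
) -> tuple[SelexExperiment, GroundTruth]:
    """Simulate cycles of selection, amplification and finite sequencing.

    Cycle 0 is a ``pool_size``-molecule pool drawn with per-base weights
    proportional to ``amp_bias``.  Each subsequent cycle reweights every pool
    oligo by ``(occupancy + nonspecific_floor) ** selection_strength``
    (selection with background binding) times its
    composition amplification factor (bias), adds any contaminant oligos at a
    relative abundance of ``contaminant_amplification ** cycle / pool_size``
    (sequence-independent geometric growth from roughly one molecule), then
    resamples a ``pool_size`` pool and sequences ``reads_per_cycle`` reads
    from it.  Both resampling steps are multinomial, so low-abundance species
    drop out and reappear exactly as finite sampling dictates.
    """
    rng = _stream(config, 2)
    amp_bias = np.asarray(config.amp_bias, dtype=float)
    amp_bias = amp_bias / amp_bias.mean()
    L = config.oligo_length
    if pwm.k > L:
        raise ValueError("PWM longer than oligo length")

    pool_draw_p = amp_bias / amp_bias.sum()
    codes = rng.choice(4, size=(config.pool_size, L), p=pool_draw_p)
    unique_codes, counts = np.unique(codes, axis=0, return_counts=True)

    contaminants = list(config.contaminant_oligos)
    for o in contaminants:
        if len(o) != L:
            raise ValueError("contaminant oligos must have the pool oligo length")
    cont_codes = (
        np.array([encode_sequence(o) for o in contaminants])
        if contaminants
        else np.empty((0, L), dtype=np.int8)
    )

    def _affinity(mat: np.ndarray) -> np.ndarray:
        return occupancy_scores_batch(pwm, mat, strand_mode="both")

    def _sample_reads(
        mat: np.ndarray, pool_counts: np.ndarray, n_reads: int
    ) -> CycleTable:
        p = pool_counts / pool_counts.sum()
        read_counts = rng.multinomial(n_reads, p)
        nz = read_counts > 0
        table = {
            _decode(mat[i]): int(read_counts[i]) for i in np.nonzero(nz)[0]
        }
        return CycleTable(table)

    cycles = [_sample_reads(unique_codes, counts, config.reads_per_cycle)]
    cycles[0].cycle_index = 0

    truth = GroundTruth(pwm=pwm, contaminants=contaminants)
    aff_all = _affinity(unique_codes)
    for row, a in zip(unique_codes, aff_all):
        truth.affinities[_decode(row)] = float(a)
    if contaminants:
        for o, a in zip(contaminants, _affinity(cont_codes)):
            truth.affinities[o] = float(a)

    pool_codes, pool_counts = unique_codes, counts
    for cycle in range(1, config.n_cycles + 1):
        aff = _affinity(pool_codes)
        weights = (
            pool_counts
            * np.power(aff + config.nonspecific_floor, config.selection_strength)
            * _composition_amp_factors(pool_codes, amp_bias)
        )
        total_w = weights.sum()
        if total_w <= 0:
            raise ValueError("all selection weights vanished; PWM has hard zeros?")
        if contaminants:
            cont_w = np.full(
                len(contaminants),
                total_w
                * (config.contaminant_amplification ** cycle)
                / config.pool_size,
            )
            all_codes = np.vstack([pool_codes, cont_codes])
            weights = np.concatenate([weights, cont_w])
        else:
            all_codes = pool_codes
        new_counts = rng.multinomial(config.pool_size, weights / weights.sum())
        keep = new_counts > 0
        pool_codes, pool_counts = all_codes[keep], new_counts[keep]
        table = _sample_reads(pool_codes, pool_counts, config.reads_per_cycle)
        table.cycle_index = cycle
        cycles.append(table)

    experiment = SelexExperiment(
        tf_name="synthetic_tf",
        oligo_length=L,
        cycles=cycles,
        seeds=[consensus_kmer(pwm)],
    )
    return experiment, truth


def kmer_affinity_table(pwm: PWM, k: int = 8) -> KmerTable:
    """Ground-truth affinity (sum occupancy, both strands) of every k-mer.

    The reference ranking against which per-cycle SELEX frequency tables can
    be judged; enumerates all 4^k words, so intended for k <= 10.
    """
    n = 4 ** k
    codes = np.array(
        list(itertools.product(range(4), repeat=k)), dtype=np.int8
    )
    scores = occupancy_scores_batch(pwm, codes, strand_mode="both")
    return KmerTable(
        {_decode(row): float(s) for row, s in zip(codes, scores)},
        k=k,
        score_kind="affinity",
    )


def gen_contaminant_oligos(
    n: int,
    length: int,
    seeds: Sequence[str],
    seed: int,
    max_mismatch: int = 1,
) -> tuple[str, ...]:
    """Random oligos guaranteed not to contain any seed (either strand,
    ``max_mismatch`` allowed) — sequence-independent contaminant species."""
    from .bias import oligo_contains_seed

    rng = np.random.default_rng(seed)
    out: list[str] = []
    while len(out) < n:
        o = _decode(rng.choice(4, size=length))
        if not oligo_contains_seed(o, list(seeds), max_mismatch):
            out.append(o)
    return tuple(out)


def gen_chip_experiment(
    pwm: PWM, config: SimulationConfig, genome_length: int
) -> tuple[list[PeakRecord], dict[str, str], GroundTruth]:
    """Synthetic genome with non-overlapping peaks and optionally planted sites.

    Peaks are laid out one per equal-width slot so their evaluation windows
    (positive [c-125,c+125), negative up to c+550) can never collide.  With
    probability ``plant_prob`` a site drawn from the PWM is written at a
    uniform offset within +-50 of the center; planted peaks receive smaller
    p-values than unplanted ones, mimicking stronger ChIP signal at real
    sites.
    """
    if genome_length < config.n_peaks * 2000:
        raise ValueError("genome_length must be >= n_peaks * 2000")
    rng = _stream(config, 3)
    probs = _background_probs(config.background_gc)
    genome_codes = rng.choice(4, size=genome_length, p=probs).astype(np.int8)

    slot = genome_length // config.n_peaks
    margin = 700  # room for the negative flank on either side
    if slot - 2 * margin <= 0:
        raise ValueError("peak slots too narrow for non-overlapping windows")
    peaks: list[PeakRecord] = []
    planted: list[tuple[str, int] | None] = []
    for i in range(config.n_peaks):
        c = i * slot + int(rng.integers(margin, slot - margin))
        plant = rng.random() < config.plant_prob
        if plant:
            site = sample_site(pwm, rng)
            offset = int(rng.integers(-50, 51 - pwm.k))
            pos = c + offset
            genome_codes[pos : pos + pwm.k] = encode_sequence(site)
            planted.append(("chr1", pos))
            pvalue = 10.0 ** -rng.uniform(6, 10)
        else:
            planted.append(None)
            pvalue = 10.0 ** -rng.uniform(2, 5)
        peaks.append(
            PeakRecord("chr1", c - 100, c + 100, pvalue=pvalue, id=f"peak{i}")
        )
    genome = {"chr1": _decode(genome_codes)}
    truth = GroundTruth(pwm=pwm, planted_positions=planted)
    return peaks, genome, truth
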