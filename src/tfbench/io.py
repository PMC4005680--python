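"""Readers and writers for the external text formats.

Matrices come in two text dialects: per-base probability lines
(``A: 0.25 0.5 ...``, the UniPROBE style) and a count matrix (one header
line, then four integer rows in A,C,G,T order).  Probe tables are 2-column
TSV (sequence, intensity).  SELEX cycles are FASTA, FASTQ (qualities
ignored) or one-oligo-per-line text with an optional ``sequence<TAB>count``
collapsed form.  Peaks are BED-like TSV with a p-value column.  All outputs
are TSV with ``#``-prefixed header comments echoing parameters, so every
writer's output round-trips through its reader.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from Bio import SeqIO

from .bias import FalseOligoReport
from .chip import PeakRecord
from .compare import ComparisonGridResult
from .pbm import EvalMetrics, ProbeTable
from .pwm import BASES, PWM, normalize_pwm
from .selex import CycleTable, KmerTable, SelexExperiment


class FormatError(ValueError):
    """Malformed input; message carries the file and line number."""


def _fail(path: Path | str, lineno: int, msg: str) -> None:
    raise FormatError(f"{path}:{lineno}: {msg}")


# ---------------------------------------------------------------- PWM files


def read_pwm(path: str | Path, pseudocount: float = 0.0, source: str = "pbm") -> PWM:
    """Read a PWM, auto-detecting the probability or count dialect."""
    path = Path(path)
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}:1: empty PWM file")
    if any(ln[:2] in ("A:", "C:", "G:", "T:") for ln in lines):
        return _read_probability_pwm(path, lines, source)
    return _read_count_pwm(path, lines, pseudocount, source)


def _read_probability_pwm(path: Path, lines: list[str], source: str) -> PWM:
    rows: dict[str, list[float]] = {}
    name = path.stem
    for i, ln in enumerate(lines, start=1):
        if ln.startswith("#") or ln.startswith(">"):
            name = ln.lstrip("#> ").strip() or name
            continue
        base, _, rest = ln.partition(":")
        base = base.strip()
        if base not in "ACGT" or len(base) != 1:
            _fail(path, i, f"expected a base row 'A: ...', got {ln!r}")
        try:
            rows[base] = [float(x) for x in rest.split()]
        except ValueError:
            _fail(path, i, f"non-numeric probability in row {base}")
    missing = set("ACGT") - set(rows)
    if missing:
        raise FormatError(f"{path}: missing base rows {sorted(missing)}")
    lengths = {len(v) for v in rows.values()}
    if len(lengths) != 1:
        raise FormatError(f"{path}: base rows have unequal lengths {sorted(lengths)}")
    probs = np.array([rows[b] for b in BASES])
    # renormalize away rounding in published matrices
    probs = probs / probs.sum(axis=0)
    return PWM(probs, name=name, source=source)


def _read_count_pwm(
    path: Path, lines: list[str], pseudocount: float, source: str
) -> PWM:
    name = path.stem
    data_rows: list[list[float]] = []
    for i, ln in enumerate(lines, start=1):
        fields = ln.split()
        try:
            data_rows.append([float(x) for x in fields])
        except ValueError:
            if data_rows:
                _fail(path, i, "non-numeric row inside the count matrix")
            name = ln.lstrip("#> ").strip() or name  # header line
    if len(data_rows) != 4:
        raise FormatError(
            f"{path}: count matrix must have 4 rows (A,C,G,T), got {len(data_rows)}"
        )
    return normalize_pwm(np.array(data_rows), pseudocount, name=name, source=source)


def write_pwm(pwm: PWM, path: str | Path) -> None:
    """Write the probability dialect: name header plus one line per base."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# {pwm.name}\n")
        for b, row in zip(BASES, pwm.probs):
            fh.write(f"{b}: " + " ".join(f"{x:.6f}" for x in row) + "\n")


# ------------------------------------------------------------- probe tables


def read_probe_table(
    path: str | Path, unique_length: int | None = 36, experiment_id: str = ""
) -> ProbeTable:
    """Read a 2-column TSV of (sequence, intensity), optional header line.

    With ``unique_length`` set, sequences are truncated to their first that
    many bases (the unique, informative region of each probe); sequences
    shorter than it are rejected.  Pass None to keep full sequences.
    """
    path = Path(path)
    sequences: list[str] = []
    intensities: list[float] = []
    with path.open() as fh:
        for i, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if not ln or ln.startswith("#"):
                continue
            fields = ln.split("\t")
            if len(fields) != 2:
                _fail(path, i, f"expected 2 tab-separated columns, got {len(fields)}")
            seq, val = fields
            if i == 1:
                try:
                    float(val)
                except ValueError:
                    continue  # header line
            try:
                intensity = float(val)
            except ValueError:
                _fail(path, i, f"non-numeric intensity {val!r}")
            seq = seq.strip().upper()
            if any(c not in "ACGTN" for c in seq):
                _fail(path, i, f"invalid probe sequence {seq!r}")
            if unique_length is not None:
                if len(seq) < unique_length:
                    _fail(
                        path, i, f"probe shorter than unique length {unique_length}"
                    )
                seq = seq[:unique_length]
            sequences.append(seq)
            intensities.append(intensity)
    if not sequences:
        raise FormatError(f"{path}: no probes found")
    return ProbeTable(
        sequences, np.array(intensities), experiment_id=experiment_id or path.stem
    )


def write_probe_table(table: ProbeTable, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("sequence\tintensity\n")
        for seq, x in zip(table.sequences, table.intensities):
            fh.write(f"{seq}\t{x:.6g}\n")


def write_metrics(
    metrics: EvalMetrics, experiment_id: str, path: str | Path
) -> None:
    with Path(path).open("w") as fh:
        fh.write("experiment_id\tspearman\tsens_1pct\tauc\n")
        rho = "NA" if metrics.spearman_on_positives is None else (
            f"{metrics.spearman_on_positives:.6f}"
        )
        fh.write(
            f"{experiment_id}\t{rho}\t{metrics.sens_at_1pct_fpr:.6f}"
            f"\t{metrics.auc:.6f}\n"
        )


# -------------------------------------------------------------- SELEX cycles


def read_cycle(
    path: str | Path, cycle_index: int = 0, expected_length: int | None = None
) -> CycleTable:
    """Read one cycle of oligos: FASTA, FASTQ, or oligo-per-line text.

    The plain-text form accepts ``sequence`` or ``sequence<TAB>count`` lines.
    Oligos are validated to a single fixed length (adapters are assumed
    already stripped); reads of any other length are rejected with a count.
    """
    path = Path(path)
    counts: dict[str, int] = {}
    with path.open() as fh:
        first = fh.read(1)
    if first == ">":
        records = ((r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta"))
        for _, seq in records:
            seq = seq.upper()
            counts[seq] = counts.get(seq, 0) + 1
    elif first == "@":
        for r in SeqIO.parse(str(path), "fastq"):
            seq = str(r.seq).upper()
            counts[seq] = counts.get(seq, 0) + 1
    else:
        with path.open() as fh:
            for i, ln in enumerate(fh, start=1):
                ln = ln.strip()
                if not ln or ln.startswith("#"):
                    continue
                fields = ln.split("\t")
                seq = fields[0].upper()
                if any(c not in "ACGTN" for c in seq):
                    _fail(path, i, f"invalid oligo {seq!r}")
                if len(fields) == 1:
                    n = 1
                elif len(fields) == 2:
                    try:
                        n = int(fields[1])
                    except ValueError:
                        _fail(path, i, f"non-integer count {fields[1]!r}")
                else:
                    _fail(path, i, f"expected 1 or 2 columns, got {len(fields)}")
                if n <= 0:
                    _fail(path, i, "count must be positive")
                counts[seq] = counts.get(seq, 0) + n
    if not counts:
        raise FormatError(f"{path}: no oligos found")
    lengths = {len(o) for o in counts}
    target = expected_length if expected_length is not None else max(
        lengths, key=lambda L: sum(n for o, n in counts.items() if len(o) == L)
    )
    rejected = sum(n for o, n in counts.items() if len(o) != target)
    if rejected:
        import logging

        logging.getLogger(__name__).warning(
            "%s: rejected %d reads not of length %d", path, rejected, target
        )
        counts = {o: n for o, n in counts.items() if len(o) == target}
    return CycleTable(counts, cycle_index=cycle_index)


def write_cycle(cycle: CycleTable, path: str | Path) -> None:
    """Write the collapsed oligo-per-line form (sequence<TAB>count)."""
    with Path(path).open("w") as fh:
        for oligo in sorted(cycle.counts):
            fh.write(f"{oligo}\t{cycle.counts[oligo]}\n")


def read_selex_experiment(
    cycle_paths: Sequence[str | Path],
    seeds: Sequence[str],
    tf_name: str = "",
) -> SelexExperiment:
    """Assemble an experiment from per-cycle files ordered cycle 0, 1, ..."""
    cycles = [read_cycle(p, cycle_index=i) for i, p in enumerate(cycle_paths)]
    return SelexExperiment(
        tf_name=tf_name,
        oligo_length=cycles[0].oligo_length,
        cycles=cycles,
        seeds=[s.upper() for s in seeds],
    )


# -------------------------------------------------------------- k-mer tables


def write_kmer_table(table: KmerTable, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write(f"# k={table.k} score_kind={table.score_kind}\n")
        fh.write("kmer\tscore\n")
        for w in sorted(table.scores):
            fh.write(f"{w}\t{table.scores[w]:.10g}\n")


def read_kmer_table(path: str | Path) -> KmerTable:
    path = Path(path)
    k = None
    score_kind = None
    scores: dict[str, float] = {}
    with path.open() as fh:
        for i, ln in enumerate(fh, start=1):
            ln = ln.strip()
            if not ln:
                continue
            if ln.startswith("#"):
                for token in ln.lstrip("# ").split():
                    key, _, val = token.partition("=")
                    if key == "k":
                        k = int(val)
                    elif key == "score_kind":
                        score_kind = val
                continue
            fields = ln.split("\t")
            if fields[0] == "kmer":
                continue
            if len(fields) != 2:
                _fail(path, i, f"expected 2 columns, got {len(fields)}")
            scores[fields[0].upper()] = float(fields[1])
    if k is None or score_kind is None:
        raise FormatError(f"{path}: missing '# k=... score_kind=...' header")
    return KmerTable(scores, k=k, score_kind=score_kind)


# --------------------------------------------------------------- ChIP inputs


def read_peaks(
    path: str | Path, pvalue_col: int = 3, neg_log10: bool = False
) -> list[PeakRecord]:
    """Read BED-like peaks: chrom, start, end, then a p-value column.

    ``pvalue_col`` is the 0-based column holding the p-value; for ENCODE
    narrowPeak pass ``pvalue_col=7, neg_log10=True`` (column 8 is -log10 p).
    """
    path = Path(path)
    peaks: list[PeakRecord] = []
    with path.open() as fh:
        for i, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if not ln or ln.startswith(("#", "track", "browser")):
                continue
            fields = ln.split("\t")
            if len(fields) <= max(2, pvalue_col):
                _fail(path, i, f"expected > {pvalue_col} columns, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
                raw = float(fields[pvalue_col])
            except ValueError:
                _fail(path, i, "non-numeric coordinate or p-value")
            pvalue = 10.0 ** (-raw) if neg_log10 else raw
            peaks.append(
                PeakRecord(fields[0], start, end, pvalue=pvalue, id=f"{path.stem}:{i}")
            )
    if not peaks:
        raise FormatError(f"{path}: no peaks found")
    return peaks


def write_peaks(peaks: Iterable[PeakRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.pvalue:.6g}\n")


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    genome = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }
    if not genome:
        raise FormatError(f"{path}: no FASTA records found")
    return genome


def write_genome_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with Path(path).open("w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ------------------------------------------------------------------- reports


def write_grid_result(result: ComparisonGridResult, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("cycle\tsource\tscore_kind\tpearson\tn_used\tn_dropped\tbest\n")
        for e in result.entries:
            is_best = e is result.best
            fh.write(
                f"{e.cycle}\t{e.source}\t{e.selex_score}\t{e.pearson:.6f}"
                f"\t{e.n_used}\t{e.n_dropped}\t{'*' if is_best else ''}\n"
            )


def write_false_oligo_report(report: FalseOligoReport, path: str | Path) -> None:
    def _fmt(x: float | None) -> str:
        return "NA" if x is None else f"{x:.4f}"

    with Path(path).open("w") as fh:
        fh.write(
            f"# false_fraction={report.false_fraction:.4f}"
            f" skewed_false={_fmt(report.skewed_fraction_false)}"
            f" skewed_true={_fmt(report.skewed_fraction_true)}"
            f" absent_prev_false={_fmt(report.absent_prev_fraction_false)}"
            f" absent_prev_true={_fmt(report.absent_prev_fraction_true)}\n"
        )
        fh.write("oligo\tpartition\tenrichment_ratio\n")
        false = set(report.false_set)
        for o in report.top_oligos:
            ratio = report.enrichment_ratios.get(o, math.nan)
            ratio_s = "inf" if math.isinf(ratio) else f"{ratio:.4g}"
            fh.write(f"{o}\t{'false' if o in false else 'true'}\t{ratio_s}\n")


# --------------------------------------------------------------------- config


DEFAULT_PARAMS = {
    "k": 8,
    "top_n": 100,
    "fpr": 0.01,
    "mad_multiplier": 4.0,
    "failure_margin": 0.1,
    "peak_n": 500,
    "pos_halfwidth": 125,
    "neg_offset": 300,
    "neg_length": 250,
}


def load_run_config(path: str | Path | None) -> dict:
    """Flat YAML key-value config; unknown keys are rejected, missing keys
    fall back to the standard analysis constants."""
    params = dict(DEFAULT_PARAMS)
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise FormatError(f"{path}: config must be a flat mapping")
        unknown = set(loaded) - set(DEFAULT_PARAMS) - {"seed", "output_dir"}
        if unknown:
            raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
        params.update(loaded)
    return params
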