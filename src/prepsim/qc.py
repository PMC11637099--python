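"""Library quality-control metrics.

Covers the four library passing criteria (total yield >= 250 ng,
concentration >= 5 ng/uL — the minimum sequence-able concentration,
adapter-dimer <= 5% by mass, and a fragment-size distribution inside
200-1000 bp), replicate summary statistics, the fluorometric
quantification-noise model (12% CV), and a toy GC-bias metric that bins
read-anchored 100 bp reference windows by integer GC percent and
normalises per-bin read counts by the mean over occupied bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio import SeqIO

from prepsim.simulate import FragmentPopulation, SimulationResult


@dataclass
class QCThresholds:
    """Pass/fail thresholds; comparisons are inclusive at boundaries."""

    min_yield_ng: float = 250.0
    min_concentration: float = 5.0   # ng/uL
    max_percent_dimer: float = 5.0
    min_in_range_fraction: float = 0.8  # mass fraction within size window
    size_range: tuple[float, float] = (200.0, 1000.0)


@dataclass
class QCReport:
    """Outcome of a library QC assessment; pass iff no rule failed."""

    yield_ng: float
    concentration: float
    percent_adapter_dimer: float
    size_in_range_fraction: float
    mean_fragment_size: Optional[float]
    passed: bool
    failed_rules: list[str] = field(default_factory=list)


def assess_library(
    result: SimulationResult | None = None,
    *,
    yield_ng: Optional[float] = None,
    concentration: Optional[float] = None,
    percent_dimer: Optional[float] = None,
    in_range_fraction: Optional[float] = None,
    mean_fragment_size: Optional[float] = None,
    thresholds: QCThresholds | None = None,
) -> QCReport:
    """Apply the library passing criteria to a simulated or measured library.

    Either pass a :class:`SimulationResult` or the measured values
    directly (explicit keywords override the simulation's numbers).
    Failures are report content, never exceptions.
    """
    th = thresholds or QCThresholds()
    if result is not None:
        if yield_ng is None:
            yield_ng = result.m_out * 1e9
        if concentration is None:
            concentration = result.C_f
        if percent_dimer is None:
            percent_dimer = result.percent_adapter_dimer
        if in_range_fraction is None:
            in_range_fraction = result.in_range_fraction
        if mean_fragment_size is None:
            mean_fragment_size = result.final_population.mean_length()
    for name, v in (("yield_ng", yield_ng), ("concentration", concentration),
                    ("percent_dimer", percent_dimer),
                    ("in_range_fraction", in_range_fraction)):
        if v is None:
            raise ValueError(f"{name} missing: pass a result or the value")
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    failed = []
    if yield_ng < th.min_yield_ng:
        failed.append(f"yield >= {th.min_yield_ng:g} ng")
    if concentration < th.min_concentration:
        failed.append(f"concentration >= {th.min_concentration:g} ng/uL")
    if percent_dimer > th.max_percent_dimer:
        failed.append(f"adapter-dimer <= {th.max_percent_dimer:g}%")
    if in_range_fraction < th.min_in_range_fraction:
        failed.append(
            f"size distribution within [{th.size_range[0]:g}, "
            f"{th.size_range[1]:g}] bp"
        )
    return QCReport(
        yield_ng=yield_ng,
        concentration=concentration,
        percent_adapter_dimer=percent_dimer,
        size_in_range_fraction=in_range_fraction,
        mean_fragment_size=mean_fragment_size,
        passed=not failed,
        failed_rules=failed,
    )


def replicate_stats(values: Sequence[float]) -> tuple[float, float, float]:
    """Mean, sample SD (n-1 denominator) and CV of replicate measurements.

    CV is NaN (flagged, not raised) when the mean is zero.
    """
    arr = np.asarray(values, dtype=float)
    if len(arr) < 2:
        raise ValueError("need at least 2 values for SD/CV")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    cv = sd / mean if mean != 0 else float("nan")
    return mean, sd, cv


def measure_concentration(
    true_conc: float,
    cv: float = 0.12,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Fluorometric quantification with multiplicative Gaussian error.

    The measured value is ``true * (1 + N(0, cv))`` truncated at zero,
    modelling the instrument's 12% quantification uncertainty.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if true_conc < 0:
        raise ValueError("true_conc must be >= 0")
    if cv == 0 or true_conc == 0:
        return true_conc
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    return max(0.0, true_conc * (1.0 + rng.normal(0.0, cv)))


def percent_adapter_dimer(pop: FragmentPopulation) -> float:
    """Adapter-dimer mass percentage, ``100 * dimer mass / total mass``."""
    total = pop.total_mass()
    if total <= 0:
        raise ValueError("population is empty; % adapter-dimer undefined")
    return 100.0 * pop.total_mass("adapter_dimer") / total


@dataclass
class GCBiasProfile:
    """Per-GC-bin read counts and normalised coverage.

    ``gc_bins`` are integer GC percents of the read-anchored reference
    windows; ``normalized_coverage`` is each bin's read count divided by
    the mean count over occupied bins, so it averages 1 by construction.
    """

    gc_bins: np.ndarray
    reads: np.ndarray
    normalized_coverage: np.ndarray
    window_size: int
    n_excluded: int  # reads whose window GC fell outside the scored range


def normalized_coverage_by_gc(
    reference: str,
    read_starts: Sequence[int],
    window: int = 100,
    gc_range: tuple[int, int] = (20, 60),
) -> GCBiasProfile:
    """GC-bias profile from read-anchored reference windows.

    Each read contributes the GC percent (rounded to an integer bin) of
    ``reference[start : start+window)``; reads whose window GC lies
    outside ``gc_range`` are excluded.  Coordinates are 0-based
    half-open on a single strand.
    """
    reference = str(reference).upper()
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(reference) < window:
        raise ValueError("reference shorter than one window")
    is_gc = np.frompyfunc(lambda c: c in "GCS", 1, 1)
    base_gc = np.asarray(is_gc(np.array(list(reference))), dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(base_gc)])
    starts = np.asarray(read_starts, dtype=np.int64)
    if len(starts) == 0:
        raise ValueError("no reads supplied")
    if starts.min() < 0 or starts.max() > len(reference) - window:
        raise ValueError("read start outside [0, len(reference) - window]")
    gc_counts = cum[starts + window] - cum[starts]
    gc_pct = np.rint(100.0 * gc_counts / window).astype(np.int64)
    in_range = (gc_pct >= gc_range[0]) & (gc_pct <= gc_range[1])
    kept = gc_pct[in_range]
    if len(kept) == 0:
        raise ValueError(f"no reads with window GC inside {gc_range}")
    bins, counts = np.unique(kept, return_counts=True)
    norm = counts / counts.mean()
    return GCBiasProfile(
        gc_bins=bins,
        reads=counts,
        normalized_coverage=norm,
        window_size=window,
        n_excluded=int((~in_range).sum()),
    )


def read_fasta(path: str | Path) -> str:
    """Read the first record of a FASTA file as an uppercase string."""
    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq).upper()


def read_starts_file(path: str | Path) -> list[int]:
    """Read one 0-based integer read start per line."""
    return [int(line) for line in Path(path).read_text().split()]
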