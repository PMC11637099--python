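"""Fragment-level Monte-Carlo simulation of the library-preparation assay.

The simulator tracks integer molecule counts per (length, species)
class through the assay pipeline — fragmentation, adapter ligation with
adapter-dimer formation, a length-selective post-ligation SPRI wash,
PCR amplification, a post-PCR SPRI wash, and adsorption/transfer losses.
Every stage is a binomial (or Poisson/branching) randomisation whose
expectation equals the corresponding factor of the deterministic
efficiency cascade, so the replicate mean of each stage's molecule
count reproduces the cascade exactly, while the population adds what
the cascade cannot express: fragment-size distributions and
adapter-dimer accounting.

SPRI size selection is modelled with a logistic retention curve in
fragment length, calibrated per wash so the population-weighted mean
retention of adapter-ligated molecules equals the composite wash
efficiency eta_wash.  Adapter-dimers (~2 adapter lengths, below the
curve's midpoint) are therefore preferentially removed, as on the real
platform.

Randomness follows a single root seed: each stage draws from its own
child stream spawned from ``numpy.random.SeedSequence(seed)``, so
results are bit-reproducible and stage-local.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from prepsim.cascade import (
    EfficiencyParams, MASS_PER_BP, N_AVOGADRO, n_input_molecules, output_mass,
)
from prepsim.protocols import AssayProtocol

SPECIES = ("insert", "adapter_ligated_insert", "adapter_dimer")
_SPECIES_CODE = {name: i for i, name in enumerate(SPECIES)}


@dataclass
class FragmentPopulation:
    """Counts of DNA molecules by integer length (bp) and species.

    ``lengths`` (bp), ``species`` (codes into :data:`SPECIES`) and
    ``counts`` are parallel integer arrays; duplicate (length, species)
    classes are collapsed on construction.
    """

    lengths: np.ndarray
    species: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=np.int64)
        self.species = np.asarray(self.species, dtype=np.int8)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if not (len(self.lengths) == len(self.species) == len(self.counts)):
            raise ValueError("lengths, species and counts must be parallel")
        if np.any(self.counts < 0) or np.any(self.lengths < 1):
            raise ValueError("counts must be >= 0 and lengths >= 1")
        self._collapse()

    def _collapse(self) -> None:
        if len(self.lengths) == 0:
            return
        # 1-D combined key (species in the high bits) for a fast unique
        keys = self.species.astype(np.int64) * (1 << 48) + self.lengths
        uniq, inverse = np.unique(keys, return_inverse=True)
        counts = np.bincount(inverse, weights=self.counts).astype(np.int64)
        keep = counts > 0
        uniq = uniq[keep]
        self.species = (uniq >> 48).astype(np.int8)
        self.lengths = uniq & ((1 << 48) - 1)
        self.counts = counts[keep]

    @classmethod
    def empty(cls) -> "FragmentPopulation":
        z = np.zeros(0, dtype=np.int64)
        return cls(z, z.copy(), z.copy())

    @classmethod
    def from_lengths(
        cls, lengths: np.ndarray, species: str = "insert"
    ) -> "FragmentPopulation":
        """Build a population from one molecule per entry of ``lengths``."""
        lengths = np.asarray(lengths, dtype=np.int64)
        code = _SPECIES_CODE[species]
        uniq, counts = np.unique(lengths, return_counts=True)
        return cls(uniq, np.full(len(uniq), code, dtype=np.int8),
                   counts.astype(np.int64))

    def total_count(self, species: Optional[str] = None) -> int:
        return int(self.counts[self._mask(species)].sum())

    def total_mass(self, species: Optional[str] = None) -> float:
        """Mass in grams, ``650 * sum(length*count) / N_A``."""
        m = self._mask(species)
        return float(
            MASS_PER_BP
            * (self.lengths[m].astype(float) * self.counts[m]).sum()
            / N_AVOGADRO
        )

    def mean_length(self, species: Optional[str] = None) -> float:
        m = self._mask(species)
        n = self.counts[m].sum()
        if n == 0:
            return float("nan")
        return float((self.lengths[m] * self.counts[m]).sum() / n)

    def select(self, species: str) -> "FragmentPopulation":
        m = self._mask(species)
        return FragmentPopulation(
            self.lengths[m], self.species[m], self.counts[m]
        )

    def _mask(self, species: Optional[str]) -> np.ndarray:
        if species is None:
            return np.ones(len(self.lengths), dtype=bool)
        return self.species == _SPECIES_CODE[species]


@dataclass
class SPRIRetentionCurve:
    """Logistic fragment-retention curve of an SPRI bead wash.

    ``retention(l) = eta_max / (1 + exp(-(l - l50)/s))``: monotone
    nondecreasing in length, at most ``eta_max``, half-maximal at
    ``l50``.  The defaults place the midpoint at the 200 bp small-
    fragment removal target of the post-PCR cleanup.
    """

    l50: float = 200.0
    s: float = 20.0
    eta_max: float = 1.0

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError("s must be > 0")
        if not 0.0 <= self.eta_max <= 1.0:
            raise ValueError("eta_max outside [0, 1]")

    def retention(self, length: np.ndarray | float) -> np.ndarray | float:
        z = (np.asarray(length, dtype=float) - self.l50) / self.s
        return self.eta_max / (1.0 + np.exp(-z))


def simulate_fragmentation(
    n_molecules: int,
    distribution: str = "lognormal",
    mean_length: float = 250.0,
    cv: float = 0.30,
    seed: int | np.random.Generator | None = None,
) -> FragmentPopulation:
    """Draw an insert population with the requested mean length.

    ``lognormal`` is parameterised by its arithmetic mean and CV
    (``sigma^2 = ln(1+cv^2)``); ``fixed`` gives all-equal lengths and
    requires ``cv == 0``.  Lengths are rounded to integer bp (min 1).
    """
    if mean_length < 1:
        raise ValueError("mean_length must be >= 1 bp")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if n_molecules < 0:
        raise ValueError("n_molecules must be >= 0")
    if n_molecules == 0:
        return FragmentPopulation.empty()
    if distribution == "fixed":
        if cv != 0:
            raise ValueError("fixed distribution requires cv == 0")
        length = max(1, int(round(mean_length)))
        return FragmentPopulation(
            np.array([length]), np.array([_SPECIES_CODE["insert"]]),
            np.array([n_molecules]),
        )
    if distribution != "lognormal":
        raise ValueError(f"unknown distribution: {distribution!r}")
    rng = _as_rng(seed)
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean_length) - sigma2 / 2.0
    draws = rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n_molecules)
    lengths = np.maximum(1, np.rint(draws).astype(np.int64))
    return FragmentPopulation.from_lengths(lengths)


def simulate_ligation(
    pop: FragmentPopulation,
    eta_lig: float,
    dimer_rate: float,
    l_A: float,
    seed: int | np.random.Generator | None = None,
) -> FragmentPopulation:
    """Adapter ligation: binomial thinning into the ligated species.

    Each insert ligates with probability ``eta_lig`` (gaining ``2*l_A``
    bp of adapter); failures stay behind as unligated inserts.
    Adapter-dimers are drawn ``Poisson(dimer_rate * input count)`` at
    length ``2*l_A``.
    """
    if not 0.0 <= eta_lig <= 1.0:
        raise ValueError("eta_lig outside [0, 1]")
    if dimer_rate < 0:
        raise ValueError("dimer_rate must be >= 0")
    rng = _as_rng(seed)
    ins = pop.select("insert")
    other = pop.counts[pop.species != _SPECIES_CODE["insert"]]
    if len(other) and other.sum() > 0:
        raise ValueError("ligation input must contain only inserts")
    ligated = rng.binomial(ins.counts, eta_lig)
    remaining = ins.counts - ligated
    dimer_len = max(1, int(round(2 * l_A)))
    n_dimers = int(rng.poisson(dimer_rate * ins.total_count())) \
        if ins.total_count() > 0 else 0
    lengths = np.concatenate([
        ins.lengths + int(round(2 * l_A)),
        ins.lengths,
        np.array([dimer_len], dtype=np.int64),
    ])
    species = np.concatenate([
        np.full(len(ins.lengths), _SPECIES_CODE["adapter_ligated_insert"]),
        np.full(len(ins.lengths), _SPECIES_CODE["insert"]),
        np.array([_SPECIES_CODE["adapter_dimer"]]),
    ]).astype(np.int8)
    counts = np.concatenate([ligated, remaining, np.array([n_dimers])])
    return FragmentPopulation(lengths, species, counts)


def calibrate_retention(
    l50: float,
    s: float,
    target_eta_wash: float,
    pop: FragmentPopulation,
) -> SPRIRetentionCurve:
    """Scale the curve so the population-mean retention equals the target.

    The count-weighted mean retention of adapter-ligated inserts is
    linear in ``eta_max``, so the calibration is an exact one-step
    solve: ``eta_max = target / mean_logistic``.  Raises if the target
    is unachievable (required ``eta_max > 1``), reporting the attainable
    maximum.
    """
    if not 0.0 < target_eta_wash <= 1.0:
        raise ValueError("target_eta_wash must be in (0, 1]")
    lib = pop.select("adapter_ligated_insert")
    if lib.total_count() == 0:
        raise ValueError("population contains no adapter-ligated inserts")
    unit = SPRIRetentionCurve(l50=l50, s=s, eta_max=1.0)
    mean_logistic = float(
        (unit.retention(lib.lengths) * lib.counts).sum() / lib.counts.sum()
    )
    eta_max = target_eta_wash / mean_logistic
    if eta_max > 1.0 + 1e-12:
        raise ValueError(
            f"wash efficiency {target_eta_wash} unachievable with "
            f"(l50={l50}, s={s}); attainable maximum is {mean_logistic:.6f}"
        )
    return SPRIRetentionCurve(l50=l50, s=s, eta_max=min(eta_max, 1.0))


def simulate_spri(
    pop: FragmentPopulation,
    curve: SPRIRetentionCurve,
    seed: int | np.random.Generator | None = None,
) -> FragmentPopulation:
    """SPRI wash: independent binomial thinning at retention(length)."""
    rng = _as_rng(seed)
    p = np.asarray(curve.retention(pop.lengths), dtype=float)
    survivors = rng.binomial(pop.counts, p)
    return FragmentPopulation(pop.lengths, pop.species, survivors)


def simulate_pcr(
    pop: FragmentPopulation,
    eta_PCR: float,
    n: int,
    mode: str = "paper",
    seed: int | np.random.Generator | None = None,
) -> FragmentPopulation:
    """PCR amplification of amplifiable species (mean ``2^n * eta_PCR``).

    Adapter-ligated inserts and adapter-dimers carry primer sites and
    amplify; bare inserts pass through unchanged.  ``"paper"`` mode
    draws ``Binomial(count * 2^n, eta_PCR)`` per class — a thinned
    2^n-fold doubling matching the cascade's PCR factor directly.
    ``"per_cycle"`` mode runs n Galton-Watson doubling cycles with
    per-cycle duplication probability ``p_c = (2^n eta_PCR)^(1/n) - 1``
    (which must lie in [0, 1]); both modes have identical expectation.
    With ``n == 0`` paper mode thins by ``eta_PCR`` while per-cycle mode
    is the identity.
    """
    if not 0.0 <= eta_PCR <= 1.0:
        raise ValueError("eta_PCR outside [0, 1]")
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = _as_rng(seed)
    amp = (pop.species != _SPECIES_CODE["insert"])
    counts = pop.counts.copy()
    if mode == "paper":
        counts[amp] = rng.binomial(pop.counts[amp] * (2 ** n), eta_PCR)
    elif mode == "per_cycle":
        if n > 0:
            p_c = (2.0 ** n * eta_PCR) ** (1.0 / n) - 1.0
            if not 0.0 <= p_c <= 1.0:
                lo, hi = 2.0 ** -n, 2.0 ** n  # eta giving p_c in [0, 1]
                raise ValueError(
                    f"per-cycle duplication probability {p_c:.4f} outside "
                    f"[0, 1]; feasible eta_PCR range is [{lo:g}, 1] for n={n}"
                )
            c = counts[amp]
            for _ in range(n):
                c = c + rng.binomial(c, p_c)
            counts[amp] = c
    else:
        raise ValueError(f"unknown PCR mode: {mode!r}")
    return FragmentPopulation(pop.lengths, pop.species, counts)


def apply_losses(
    pop: FragmentPopulation,
    F_ads: float,
    F_LT: float,
    seed: int | np.random.Generator | None = None,
) -> FragmentPopulation:
    """Adsorption and transfer losses: survival ``(1-F_ads)(1-F_LT)``."""
    for name, v in (("F_ads", F_ads), ("F_LT", F_LT)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} outside [0, 1]")
    rng = _as_rng(seed)
    p = (1.0 - F_ads) * (1.0 - F_LT)
    return FragmentPopulation(
        pop.lengths, pop.species, rng.binomial(pop.counts, p)
    )


@dataclass
class SimulationOptions:
    """Desk-scale knobs of the assay simulator.

    ``n_founders`` simulated input molecules stand in for the ~1e10-1e11
    real input molecules; all stage expectations are linear in the
    count, so results scale exactly and reported masses are multiplied
    by the founder-to-real ratio.  The input fragment-length law
    defaults to lognormal with CV 0.30 around the assay's mean insert
    size; ``dimer_rate`` is the expected adapter-dimers formed per input
    molecule during ligation (most are removed by the washes).
    """

    n_founders: int = 100_000
    distribution: str = "lognormal"
    length_cv: float = 0.30
    dimer_rate: float = 1.0
    l50: float = 200.0
    s: float = 20.0
    pcr_mode: str = "paper"
    histogram_bin_width: int = 50


@dataclass
class SimulationResult:
    """Outcome of one simulated assay run."""

    final_population: FragmentPopulation
    m_out: float                 # sequence-able library mass, g (real scale)
    C_f: float                   # final concentration, ng/uL
    percent_adapter_dimer: float
    histogram: list[tuple[tuple[int, int], float]]  # (bin range bp, mass frac)
    in_range_fraction: float     # mass fraction inside [200, 1000] bp
    seed: Optional[int]
    scale: float                 # real molecules represented per simulated one
    stage_counts: dict[str, int] = field(default_factory=dict)


def simulate_assay(
    protocol: AssayProtocol,
    params: EfficiencyParams,
    options: SimulationOptions | None = None,
    seed: int | None = None,
) -> SimulationResult:
    """Run the full stochastic assay pipeline once.

    Pipeline order: fragmentation (the mechanical assay starts from
    pre-sheared input, the enzymatic assay fragments on-platform — both
    reduce to drawing the insert-length population), adapter ligation,
    post-ligation SPRI wash, PCR, post-PCR SPRI wash, and adsorption/
    transfer losses.  Each SPRI wash is calibrated against the current
    population so its count-mean retention equals ``eta_wash`` — the two
    purifications follow the same protocol and achieve the same
    composite efficiency.

    The reported ``m_out``/``C_f`` convert the final adapter-ligated
    molecule count with the same mass convention as the deterministic
    cascade, so their expectation equals the cascade's output exactly;
    the per-length population mass (which the histogram and the
    adapter-dimer percentage use) is available from
    ``final_population``.
    """
    opts = options or SimulationOptions()
    root = np.random.SeedSequence(seed)
    # One child stream per stochastic stage, in fixed pipeline order:
    # fragmentation, ligation, wash 1, PCR, wash 2, losses.
    streams = [np.random.default_rng(s) for s in root.spawn(6)]

    pop = simulate_fragmentation(
        opts.n_founders, opts.distribution, params.l_bpi,
        0.0 if opts.distribution == "fixed" else opts.length_cv,
        seed=streams[0],
    )
    stage_counts = {"input": pop.total_count()}

    pop = simulate_ligation(pop, params.eta_lig, opts.dimer_rate,
                            params.l_A, seed=streams[1])
    stage_counts["ligated"] = pop.total_count("adapter_ligated_insert")

    curve1 = _calibrated_or_flat(opts, params.eta_wash, pop)
    pop = simulate_spri(pop, curve1, seed=streams[2])
    stage_counts["post_wash1"] = pop.total_count("adapter_ligated_insert")

    pop = simulate_pcr(pop, params.eta_PCR, params.n, mode=opts.pcr_mode,
                       seed=streams[3])
    stage_counts["post_pcr"] = pop.total_count("adapter_ligated_insert")

    # Recalibrate on the current population: wash 2 follows the same
    # protocol as wash 1, so it achieves the same composite efficiency.
    curve2 = _calibrated_or_flat(opts, params.eta_wash, pop)
    pop = simulate_spri(pop, curve2, seed=streams[4])

    pop = apply_losses(pop, params.F_ads, params.F_LT, seed=streams[5])
    stage_counts["output"] = pop.total_count("adapter_ligated_insert")

    scale = n_input_molecules(params.m_in, params.l_bpi) / opts.n_founders
    n_library = pop.total_count("adapter_ligated_insert") * scale
    m_out = output_mass(n_library, params.l_bpi, params.l_A)
    C_f = m_out * 1e9 / params.V_RsB

    dimer_mass = pop.total_mass("adapter_dimer")
    total_mass = pop.total_mass()
    pct_dimer = 100.0 * dimer_mass / total_mass if total_mass > 0 else 0.0

    hist, in_range = _histogram(pop, opts.histogram_bin_width)
    return SimulationResult(
        final_population=pop,
        m_out=m_out,
        C_f=C_f,
        percent_adapter_dimer=pct_dimer,
        histogram=hist,
        in_range_fraction=in_range,
        seed=seed,
        scale=scale,
        stage_counts=stage_counts,
    )


def electropherogram(
    pop: FragmentPopulation, bin_width: int = 50
) -> tuple[list[tuple[tuple[int, int], float]], float]:
    """Mass-weighted length histogram, emulating a capillary-CE trace.

    Returns ``(bins, in_range_fraction)`` where ``bins`` is a list of
    ``((lo, hi), mass_fraction)`` over occupied half-open length bins
    and ``in_range_fraction`` is the mass fraction inside the 200-1000
    bp library window.  Fractions sum to 1 for a nonempty population;
    an empty population yields an empty histogram (flagged by the empty
    list, not an error).
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    return _histogram(pop, bin_width)


def _histogram(
    pop: FragmentPopulation, bin_width: int
) -> tuple[list[tuple[tuple[int, int], float]], float]:
    if pop.total_count() == 0:
        return [], 0.0
    mass = pop.lengths.astype(float) * pop.counts  # per-class, up to 650/N_A
    total = mass.sum()
    bins = (pop.lengths // bin_width).astype(np.int64)
    out: dict[int, float] = {}
    for b, m in zip(bins, mass):
        out[int(b)] = out.get(int(b), 0.0) + float(m)
    hist = [
        ((b * bin_width, (b + 1) * bin_width), m / total)
        for b, m in sorted(out.items())
    ]
    in_range = float(
        mass[(pop.lengths >= 200) & (pop.lengths <= 1000)].sum() / total
    )
    return hist, in_range


def _calibrated_or_flat(
    opts: SimulationOptions, eta_wash: float, pop: FragmentPopulation
) -> SPRIRetentionCurve:
    """Calibrated wash curve; degenerate populations (no adapter-ligated
    molecules left, e.g. eta_lig = 0) fall back to a curve capped at the
    composite efficiency so the wash still removes short fragments."""
    if pop.total_count("adapter_ligated_insert") == 0:
        return SPRIRetentionCurve(l50=opts.l50, s=opts.s, eta_max=eta_wash)
    return calibrate_retention(opts.l50, opts.s, eta_wash, pop)


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
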