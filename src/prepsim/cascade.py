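"""Deterministic library-preparation efficiency cascade.

The cascade maps an input DNA mass through the stage efficiencies of a
library-preparation assay to a theoretical final library concentration:

    N_DNA = m_in * N_A / (650 * <l_bpi>)            input molecules
    N_AL  = eta_lig * N_DNA                          adapter-ligated
    N_PCR = 2^n * eta_wash * eta_AL * eta_PCR * N_AL post-PCR
    N_out = N_PCR * eta_wash * (1-F_ads) * (1-F_LT)  final library
    m_out = 650 * (N_out/N_A) * l_bpi^2/(l_bpi+2 l_A)  output mass
    C_f   = m_out / V_RsB                            final concentration

with N_A Avogadro's number and 650 g/mol the molar mass of one base
pair.  eta_lig, eta_wash and eta_PCR are the ligation, composite SPRI
wash (= bead binding x elution x bead retention) and PCR efficiencies;
F_ads and F_LT are fractions lost to tubing adsorption and liquid
transfers.  The wash efficiency enters twice because the post-ligation
and post-PCR purifications follow the same protocol.

Two mass-conversion conventions are provided.  The default
(``"as_printed"``) is the published model form above, which the
reference parameter tables reproduce; ``"physical"`` uses the molar
mass of the full adapter-ligated molecule, 650*(N_out/N_A)*(l_bpi+2 l_A),
which is the convention the fragment-level simulator's population mass
follows.  See docs/methods.md for the discussion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

from scipy.optimize import brentq

#: Avogadro's number, 1/mol.
N_AVOGADRO = 6.022e23
#: Molar mass of one DNA base pair, g/mol.
MASS_PER_BP = 650.0

_EFFICIENCY_FIELDS = ("eta_lig", "eta_wash", "eta_PCR", "eta_AL")


@dataclass
class EfficiencyParams:
    """All inputs of the efficiency cascade.

    Masses in grams, lengths in bp, volumes in uL, efficiencies and loss
    fractions dimensionless in [0, 1].  ``eta_AL`` is an extra
    post-ligation survival factor in the PCR step; it defaults to 1 (the
    value that reproduces the reference tables) but is exposed so users
    can model additional pre-PCR losses.  If the wash decomposition
    ``eta_bb * eta_e * eta_br`` is fully specified it must equal
    ``eta_wash``.
    """

    m_in: float          # input DNA mass, g
    l_bpi: float         # mean input fragment length, bp
    eta_lig: float       # ligation efficiency
    eta_wash: float      # composite SPRI wash efficiency
    eta_PCR: float       # PCR efficiency
    n: int               # number of PCR cycles
    F_ads: float         # fraction lost to adsorption
    F_LT: float          # fraction lost in liquid transfers
    l_A: float           # single-adapter length, bp
    V_RsB: float         # final resuspension volume, uL
    eta_AL: float = 1.0
    eta_bb: Optional[float] = None  # bead binding
    eta_br: Optional[float] = None  # bead retention
    eta_e: Optional[float] = None   # elution

    def __post_init__(self) -> None:
        if self.m_in < 0:
            raise ValueError("m_in must be >= 0")
        if self.l_bpi < 1:
            raise ValueError("l_bpi must be >= 1 bp")
        if self.V_RsB <= 0:
            raise ValueError("V_RsB must be > 0")
        if self.n < 0:
            raise ValueError("n must be >= 0")
        for name in ("eta_lig", "eta_wash", "eta_PCR", "eta_AL",
                     "F_ads", "F_LT"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        components = (self.eta_bb, self.eta_br, self.eta_e)
        if all(c is not None for c in components):
            prod = self.eta_bb * self.eta_br * self.eta_e
            if not math.isclose(prod, self.eta_wash, rel_tol=1e-9, abs_tol=1e-12):
                raise ValueError(
                    "eta_bb*eta_br*eta_e = "
                    f"{prod:.6g} does not equal eta_wash = {self.eta_wash:.6g}"
                )


@dataclass
class CascadeResult:
    """All computed quantities of one cascade evaluation."""

    N_DNA: float   # input molecules
    N_AL: float    # adapter-ligated molecules
    N_PCR: float   # post-PCR molecules
    N_out: float   # final-library molecules
    m_out: float   # output mass, g
    C_f: float     # final concentration, ng/uL


#: Published parameter sets for the two assays (mass in g).
_TABLE = {
    "mechanical": dict(
        m_in=20e-9, l_bpi=260.0, eta_lig=0.60, eta_wash=0.73, eta_PCR=0.95,
        n=8, F_ads=0.05, F_LT=0.15, l_A=70.0, V_RsB=33.0,
    ),
    "enzymatic": dict(
        m_in=50e-9, l_bpi=250.0, eta_lig=0.65, eta_wash=0.77, eta_PCR=0.95,
        n=8, F_ads=0.05, F_LT=0.15, l_A=75.0, V_RsB=22.0,
    ),
}


def table_params(assay: str, **overrides) -> EfficiencyParams:
    """Return the published efficiency parameters for one assay.

    ``assay`` is ``"mechanical"`` or ``"enzymatic"``; keyword overrides
    replace individual fields.
    """
    try:
        base = dict(_TABLE[assay])
    except KeyError:
        raise KeyError(
            f"no such assay: {assay!r} (known: {sorted(_TABLE)})"
        ) from None
    base.update(overrides)
    return EfficiencyParams(**base)


def n_input_molecules(m_in: float, l_bpi: float) -> float:
    """Number of input DNA molecules, ``m_in N_A / (650 <l_bpi>)``."""
    if l_bpi <= 0:
        raise ValueError("l_bpi must be > 0")
    if m_in < 0:
        raise ValueError("m_in must be >= 0")
    return m_in * N_AVOGADRO / (MASS_PER_BP * l_bpi)


def adapter_ligated(N_DNA: float, eta_lig: float) -> float:
    """Adapter-ligated molecule count, ``eta_lig * N_DNA``."""
    _check_fraction("eta_lig", eta_lig)
    if N_DNA < 0:
        raise ValueError("N_DNA must be >= 0")
    return eta_lig * N_DNA


def post_pcr_count(
    N_AL: float, eta_wash: float, eta_PCR: float, n: int, eta_AL: float = 1.0
) -> float:
    """Post-PCR molecule count, ``2^n eta_wash eta_AL eta_PCR N_AL``."""
    if n < 0:
        raise ValueError("n must be >= 0")
    for name, v in (("eta_wash", eta_wash), ("eta_PCR", eta_PCR),
                    ("eta_AL", eta_AL)):
        _check_fraction(name, v)
    return (2.0 ** n) * eta_wash * eta_AL * eta_PCR * N_AL


def final_output_count(
    N_PCR: float, eta_wash: float, F_ads: float, F_LT: float
) -> float:
    """Final-library molecule count, ``N_PCR eta_wash (1-F_ads)(1-F_LT)``."""
    for name, v in (("eta_wash", eta_wash), ("F_ads", F_ads), ("F_LT", F_LT)):
        _check_fraction(name, v)
    return N_PCR * eta_wash * (1.0 - F_ads) * (1.0 - F_LT)


def output_mass(
    N_out: float, l_bpi: float, l_A: float, formula: str = "as_printed"
) -> float:
    """Convert the final molecule count to output mass in grams.

    ``formula="as_printed"`` uses the published model form,
    ``650 (N_out/N_A) l_bpi^2/(l_bpi + 2 l_A)``; ``formula="physical"``
    uses the molar mass of the adapter-ligated molecule,
    ``650 (N_out/N_A) (l_bpi + 2 l_A)``.
    """
    if N_out < 0:
        raise ValueError("N_out must be >= 0")
    moles = N_out / N_AVOGADRO
    if formula == "as_printed":
        return MASS_PER_BP * moles * l_bpi * l_bpi / (l_bpi + 2.0 * l_A)
    if formula == "physical":
        return MASS_PER_BP * moles * (l_bpi + 2.0 * l_A)
    raise ValueError(f"unknown mass formula: {formula!r}")


def final_concentration(m_out: float, V_RsB: float) -> float:
    """Final library concentration in ng/uL from mass in g and volume in uL."""
    if V_RsB <= 0:
        raise ValueError("V_RsB must be > 0")
    return m_out * 1e9 / V_RsB


def run_cascade(
    params: EfficiencyParams, mass_formula: str = "as_printed"
) -> CascadeResult:
    """Evaluate the full cascade, exposing every intermediate."""
    N_DNA = n_input_molecules(params.m_in, params.l_bpi)
    N_AL = adapter_ligated(N_DNA, params.eta_lig)
    N_PCR = post_pcr_count(
        N_AL, params.eta_wash, params.eta_PCR, params.n, params.eta_AL
    )
    N_out = final_output_count(N_PCR, params.eta_wash, params.F_ads, params.F_LT)
    m_out = output_mass(N_out, params.l_bpi, params.l_A, formula=mass_formula)
    C_f = final_concentration(m_out, params.V_RsB)
    return CascadeResult(N_DNA, N_AL, N_PCR, N_out, m_out, C_f)


@dataclass
class InversionResult:
    """Efficiency recovered from an observed concentration.

    ``at_boundary`` is set when the observation lies outside the range
    the cascade can attain on [0, 1], in which case ``value`` is the
    nearer boundary.
    """

    value: float
    at_boundary: bool = False


def invert_for_efficiency(
    observed_C_f: float,
    params: EfficiencyParams,
    unknown: str,
    mass_formula: str = "as_printed",
    tol: float = 1e-6,
) -> InversionResult:
    """Solve for one unknown efficiency from an observed concentration.

    ``unknown`` names exactly one of ``eta_lig``, ``eta_wash``,
    ``eta_PCR`` or ``eta_AL``; the corresponding field of ``params`` is
    ignored.  C_f is strictly monotone increasing in each single
    efficiency (eta_wash enters squared), so the root on [0, 1] is
    unique and found by bracketing bisection to absolute tolerance
    ``tol``.  Observations outside the attainable range return the
    boundary value flagged with ``at_boundary``.
    """
    if unknown not in _EFFICIENCY_FIELDS:
        raise ValueError(
            f"unknown efficiency must be one of {_EFFICIENCY_FIELDS}, "
            f"got {unknown!r}"
        )
    if observed_C_f < 0:
        raise ValueError("observed_C_f must be >= 0")

    def forward(value: float) -> float:
        p = replace(params, **{unknown: value})
        return run_cascade(p, mass_formula=mass_formula).C_f

    lo, hi = forward(0.0), forward(1.0)
    if observed_C_f <= lo:
        return InversionResult(0.0, at_boundary=observed_C_f < lo)
    if observed_C_f >= hi:
        return InversionResult(1.0, at_boundary=observed_C_f > hi)
    root = brentq(lambda x: forward(x) - observed_C_f, 0.0, 1.0, xtol=tol)
    return InversionResult(float(root))


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name}={value} outside [0, 1]")
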