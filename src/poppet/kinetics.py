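"""Hydrogen-exchange kinetics.

Implements the two-state Linderstrom-Lang model

.. math::

    k_{ex} = \\frac{k_{open} \\, k_{int}}{k_{close} + k_{open} + k_{int}}

with its EX2 limit :math:`k_{ex} = K_{open} k_{int}` (refolding much faster
than chemical exchange) and EX1 limit :math:`k_{ex} = k_{open}` (exchange
within one opening event), the algebra linking the exchange rate to the
protection factor :math:`PF \\approx 1/K_{open} = k_{int}/k_{ex}` and to the
opening free energy :math:`\\Delta G_{ex} = RT \\ln PF`, and intrinsic
(unstructured-chain) exchange rates from the Bai et al. poly-DL-alanine
parameterization for exchange into D2O.

``logPF`` is base-10 throughout the public interface; natural logs are used
only internally and converted explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "R_KCAL",
    "INFINITE_PROTECTION",
    "IntrinsicRateParams",
    "ExchangeKinetics",
    "PFRecord",
    "NoAmideHydrogenError",
    "ExcludedResidueError",
    "UndefinedRateError",
    "load_bai_params",
    "intrinsic_rate",
    "intrinsic_rates",
    "exchange_rate",
    "pf_from_rates",
    "logpf",
    "pf_from_logpf",
    "dg_from_pf",
]

#: Gas constant in kcal/(mol K).
R_KCAL = 1.9872e-3

#: Sentinel protection factor for a residue that never exchanges (k_ex = 0).
INFINITE_PROTECTION = math.inf

LN10 = math.log(10.0)


class NoAmideHydrogenError(ValueError):
    """Proline (or another residue without an amide H) was requested."""


class ExcludedResidueError(ValueError):
    """The chain-initial residue: its exchange cannot be recorded."""


class UndefinedRateError(ValueError):
    """All rate constants are zero; the exchange rate is undefined."""


@dataclass(frozen=True)
class IntrinsicRateParams:
    """Reference constants and side-chain factors for intrinsic rates.

    Reference rates are for poly-DL-alanine in D2O at ``t_ref``; the
    per-residue factors (log10 units) adjust acid/base/water catalysis for
    the side chains flanking each amide.  Rates are handled internally in
    1/min (the tables' native unit) and returned in 1/s.
    """

    acid_l: dict
    acid_r: dict
    base_l: dict
    base_r: dict
    log_ka_ref: float = 1.62     # log10, 1/(M min), acid catalysis
    log_kb_ref: float = 10.05    # log10, 1/(M min), base catalysis
    log_kw_ref: float = -1.5     # log10, 1/min, water catalysis
    pkd: float = 15.05           # ion product of D2O at t_ref
    t_ref: float = 293.0         # K
    ea_acid: float = 14.0        # kcal/mol activation energies
    ea_base: float = 17.0
    ea_water: float = 19.0


def load_bai_params() -> IntrinsicRateParams:
    """Load the packaged Bai-style side-chain factor table."""
    with resources.files("poppet").joinpath("data/bai1993_d2o.csv").open() as fh:
        df = pd.read_csv(fh, comment="#")
    cols = {}
    for col in ("acid_l", "acid_r", "base_l", "base_r"):
        cols[col] = {
            str(r.aa): float(getattr(r, col))
            for r in df.itertuples(index=False)
            if pd.notna(getattr(r, col))
        }
    return IntrinsicRateParams(**cols)


_DEFAULT_PARAMS: IntrinsicRateParams | None = None


def _default_params() -> IntrinsicRateParams:
    global _DEFAULT_PARAMS
    if _DEFAULT_PARAMS is None:
        _DEFAULT_PARAMS = load_bai_params()
    return _DEFAULT_PARAMS


def _arrhenius(ea: float, temperature: float, t_ref: float) -> float:
    return math.exp(-ea / R_KCAL * (1.0 / temperature - 1.0 / t_ref))


def intrinsic_rate(sequence: str, position: int, pd_value: float = 7.0,
                   temperature: float = 293.15,
                   params: IntrinsicRateParams | None = None,
                   nterm: bool = True, cterm: bool = True) -> float:
    """Intrinsic exchange rate ``k_int`` (1/s) of one amide hydrogen.

    Parameters
    ----------
    sequence
        1-letter amino-acid sequence of the chain or peptide.
    position
        1-based position of the amide; position 1 is rejected because the
        chain-initial amide's exchange cannot be recorded.
    pd_value
        pD of the D2O solvent (pH-meter reading corrected).
    nterm, cterm
        Whether the sequence ends carry free (charged) termini; disable for
        interior fragments of a longer chain.

    The rate is the sum of acid-, base- and water-catalysed terms, each
    scaled by the side-chain factors of the residue itself and of its
    preceding residue and Arrhenius-corrected to ``temperature``.
    """
    params = params or _default_params()
    sequence = sequence.upper()
    if position < 1 or position > len(sequence):
        raise IndexError(f"position {position} outside sequence of "
                         f"length {len(sequence)}")
    if position == 1:
        raise ExcludedResidueError(
            "the first residue's exchange cannot be recorded "
            "(very fast back exchange)")
    aa = sequence[position - 1]
    prev = sequence[position - 2]
    if aa == "P":
        raise NoAmideHydrogenError("proline has no backbone amide hydrogen")
    for res in (aa, prev):
        if res not in params.acid_r and res not in params.acid_l:
            raise KeyError(f"no intrinsic-rate factors for residue {res!r}")

    log_fa = params.acid_l.get(aa, 0.0) + params.acid_r.get(prev, 0.0)
    log_fb = params.base_l.get(aa, 0.0) + params.base_r.get(prev, 0.0)
    if nterm and position == 2:
        log_fa += params.acid_r.get("Nterm", 0.0)
        log_fb += params.base_r.get("Nterm", 0.0)
    if cterm and position == len(sequence):
        log_fa += params.acid_l.get("Cterm", 0.0)
        log_fb += params.base_l.get("Cterm", 0.0)

    conc_d = 10.0 ** (-pd_value)
    conc_od = 10.0 ** (pd_value - params.pkd)
    k_acid = 10.0 ** (params.log_ka_ref + log_fa) * conc_d \
        * _arrhenius(params.ea_acid, temperature, params.t_ref)
    k_base = 10.0 ** (params.log_kb_ref + log_fb) * conc_od \
        * _arrhenius(params.ea_base, temperature, params.t_ref)
    k_water = 10.0 ** (params.log_kw_ref + log_fb) \
        * _arrhenius(params.ea_water, temperature, params.t_ref)
    return (k_acid + k_base + k_water) / 60.0  # 1/min -> 1/s


def intrinsic_rates(sequence: str, pd_value: float = 7.0,
                    temperature: float = 293.15,
                    params: IntrinsicRateParams | None = None,
                    nterm: bool = True, cterm: bool = True
                    ) -> dict[int, float]:
    """``k_int`` for every exchanging position (2..n, prolines skipped)."""
    out: dict[int, float] = {}
    for pos in range(2, len(sequence) + 1):
        if sequence[pos - 1].upper() == "P":
            continue
        out[pos] = intrinsic_rate(sequence, pos, pd_value, temperature,
                                  params, nterm=nterm, cterm=cterm)
    return out


# ---------------------------------------------------------------------------
# Two-state exchange algebra
# ---------------------------------------------------------------------------

def exchange_rate(k_open: float, k_close: float, k_int: float) -> float:
    """Observed exchange rate of the two-state opening model."""
    if min(k_open, k_close, k_int) < 0:
        raise ValueError("rate constants must be non-negative")
    denom = k_close + k_open + k_int
    if denom == 0.0:
        raise UndefinedRateError("all rate constants are zero")
    return k_open * k_int / denom


def pf_from_rates(k_int: float, k_ex: float) -> float:
    """Protection factor ``PF = k_int / k_ex`` (inverse opening constant)."""
    if k_int < 0 or k_ex < 0:
        raise ValueError("rates must be non-negative")
    if k_ex == 0.0:
        return INFINITE_PROTECTION
    return k_int / k_ex


def logpf(pf: float) -> float:
    """Base-10 log of a protection factor."""
    if pf <= 0:
        raise ValueError("PF must be positive")
    return math.log10(pf)


def pf_from_logpf(log_pf: float) -> float:
    return 10.0 ** log_pf


def dg_from_pf(pf: float, temperature: float = 293.15) -> float:
    """Opening free energy ``DeltaG_ex = R T ln PF`` in kcal/mol."""
    if pf <= 0:
        raise ValueError("PF must be positive")
    return R_KCAL * temperature * math.log(pf)


@dataclass(frozen=True)
class ExchangeKinetics:
    """Rate constants of one amide with derived quantities."""

    k_open: float
    k_close: float
    k_int: float

    def __post_init__(self):
        if min(self.k_open, self.k_close, self.k_int) < 0:
            raise ValueError("rates must be non-negative")

    @property
    def k_ex(self) -> float:
        return exchange_rate(self.k_open, self.k_close, self.k_int)

    @property
    def K_open(self) -> float:
        if self.k_close == 0.0:
            return math.inf
        return self.k_open / self.k_close

    @property
    def pf(self) -> float:
        return pf_from_rates(self.k_int, self.k_ex)


@dataclass
class PFRecord:
    """Measured or predicted protection of one residue."""

    chain: str
    residue: int
    log_pf: float                  # base-10
    k_int: float | None = None     # 1/s
    source: str = "measured"       # measured | poppet | phenomenological | corex

    @property
    def pf(self) -> float:
        return pf_from_logpf(self.log_pf)

    def dg_ex(self, temperature: float = 293.15) -> float:
        return dg_from_pf(self.pf, temperature)
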