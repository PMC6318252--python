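"""Forward simulation of deuterium uptake from protection factors.

Under EX2-style single-exponential kinetics the expected deuterium content
of residue *i* after labelling time *t* is

.. math::

    D_i(t) = 1 - \\exp\\{ -(k_{int,i} / PF_i) \\, t \\}

and the peptide-level content is the sum over residues 2..n (the
chain-initial amide back-exchanges too fast to record; prolines carry no
amide hydrogen and contribute zero).  An optional scalar back-exchange
factor rescales the total without modelling the loss mechanism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .structure_io import PeptideDef

__all__ = [
    "DeuterationProfile",
    "residue_uptake",
    "peptide_uptake",
    "make_time_grid",
    "profile_difference",
]

SECONDS_PER_DAY = 86400.0


@dataclass
class DeuterationProfile:
    """Expected deuterons of one peptide over a labelling time grid."""

    peptide_id: str
    times: np.ndarray                     # seconds, ascending
    d: np.ndarray                         # expected deuterons per time point
    per_residue: dict[int, np.ndarray] = field(default_factory=dict)
    n_exchanging: int = 0
    source: str = "measured"

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.d = np.asarray(self.d, float)
        if self.times.shape != self.d.shape:
            raise ValueError("times and D must have identical shape")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be ascending")


def residue_uptake(k_int: float, pf: float, t) -> float | np.ndarray:
    """Fractional deuteration of one amide, in [0, 1].

    An infinite protection factor (the never-exchanging sentinel) gives 0
    at every finite time.
    """
    if k_int < 0:
        raise ValueError("k_int must be non-negative")
    if not pf > 0:
        raise ValueError("PF must be positive")
    t = np.asarray(t, float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    if math.isinf(pf):
        return np.zeros_like(t) if t.ndim else 0.0
    out = 1.0 - np.exp(-(k_int / pf) * t)
    return out if t.ndim else float(out)


def peptide_uptake(peptide: PeptideDef,
                   log_pf: dict[int, float],
                   k_int: dict[int, float],
                   times,
                   back_exchange: float = 1.0,
                   source: str = "measured") -> DeuterationProfile:
    """Expected deuterium content of a peptide over a time grid.

    ``log_pf`` and ``k_int`` map residue numbers to base-10 logPF and to
    intrinsic rates (1/s).  Residue ``start`` (position 1 of the peptide)
    is excluded; prolines contribute zero; any other residue missing from
    either map raises a :class:`KeyError` — no silent imputation.
    """
    times = np.asarray(times, float)
    exchanging: list[int] = []
    for offset, res in enumerate(peptide.residues):
        if offset == 0:
            continue  # first residue: exchange not recordable
        if peptide.sequence[offset].upper() == "P":
            continue
        exchanging.append(res)
    missing = [r for r in exchanging if r not in log_pf or r not in k_int]
    if missing:
        raise KeyError(
            f"peptide {peptide.peptide_id}: no PF/k_int for residues "
            + ", ".join(map(str, missing)))
    per_residue: dict[int, np.ndarray] = {}
    total = np.zeros_like(times)
    for res in exchanging:
        d = residue_uptake(k_int[res], 10.0 ** log_pf[res], times)
        per_residue[res] = d
        total = total + d
    return DeuterationProfile(
        peptide_id=peptide.peptide_id, times=times,
        d=back_exchange * total, per_residue=per_residue,
        n_exchanging=len(exchanging), source=source)


def make_time_grid(n_points: int = 16, t_min: float = 30.0,
                   t_max: float = 16 * SECONDS_PER_DAY,
                   spacing: str = "geometric") -> np.ndarray:
    """Labelling time grid in seconds, default 16 points from 30 s to 16 d."""
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if not 0 < t_min < t_max:
        raise ValueError("need 0 < t_min < t_max")
    if spacing == "geometric":
        return np.geomspace(t_min, t_max, n_points)
    if spacing == "linear":
        return np.linspace(t_min, t_max, n_points)
    raise ValueError("spacing must be 'geometric' or 'linear'")


def profile_difference(a: DeuterationProfile, b: DeuterationProfile
                       ) -> tuple[np.ndarray, float, float]:
    """Signed per-time differences ``a - b`` with their min and max."""
    if a.peptide_id != b.peptide_id:
        raise ValueError(f"profiles are for different peptides "
                         f"({a.peptide_id!r} vs {b.peptide_id!r})")
    if a.times.shape != b.times.shape or not np.allclose(a.times, b.times):
        raise ValueError("profiles have mismatching time grids")
    diff = a.d - b.d
    return diff, float(diff.min()), float(diff.max())
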