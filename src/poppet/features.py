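"""Per-residue structural covariates of the protection-factor model.

For each backbone amide hydrogen this module computes:

* **burial** ``N_i^C`` — the number of non-hydrogen atoms within a cutoff
  (default 6.5 A, inclusive) of the amide nitrogen, a packing-density proxy;
* **secondary-structure category** — ``helix`` (alpha or 3/10), ``beta-sheet``
  (strand or bridge) or ``no``, from the structure's HELIX/SHEET spans;
* **hydrogen-bond category** and count ``N_i^H`` — a geometric donor/acceptor
  criterion on the amide N-H against backbone O, side-chain O and water O
  acceptors;
* **HX-enabling motion category** — ``L`` (local fluctuations), ``UD``
  (unfolding detected by denaturant dependence) or ``UD+EX1`` (global
  unfolding, strong linear denaturant dependence), classified from a
  ``DeltaG_ex`` versus denaturant series.  ``EX1`` is an experimental
  elevated-pH label and is only ever supplied via annotation tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm

from .structure_io import (
    HBOND_CATEGORIES,
    MOTION_CATEGORIES,
    SS_CATEGORIES,
    Atom,
    ProteinStructure,
)

__all__ = [
    "ResidueFeatures",
    "DenaturantSeries",
    "HBondCriteria",
    "FeatureUnavailableError",
    "compute_burial",
    "ss_category",
    "hbond_category",
    "classify_motion",
    "build_features",
]

BACKBONE_NAMES = ("N", "CA", "C", "O")


class FeatureUnavailableError(ValueError):
    """A structural feature cannot be computed (e.g. missing backbone N)."""


@dataclass
class ResidueFeatures:
    """Covariate vector for one backbone amide hydrogen."""

    chain: str
    residue: int
    aa: str = "X"                       # 1-letter code
    burial: int = 0                     # N_i^C, heavy atoms within cutoff
    ss: str = "no"                      # SS_CATEGORIES
    hbond: str = "no"                   # HBOND_CATEGORIES
    hbond_count: int = 0                # N_i^H, for the phenomenological model
    motion: str | None = None           # MOTION_CATEGORIES or unset
    exchanging: bool = True             # False for Pro and chain-initial residues

    def __post_init__(self):
        if self.burial < 0 or self.hbond_count < 0:
            raise ValueError("burial and hbond_count must be non-negative")
        if self.ss not in SS_CATEGORIES:
            raise ValueError(f"ss must be one of {SS_CATEGORIES}")
        if self.hbond not in HBOND_CATEGORIES:
            raise ValueError(f"hbond must be one of {HBOND_CATEGORIES}")
        if self.motion is not None and self.motion not in MOTION_CATEGORIES:
            raise ValueError(f"motion must be one of {MOTION_CATEGORIES}")
        if self.hbond != "no" and self.hbond_count < 1:
            raise ValueError("hbond_count must be >= 1 when an H-bond is assigned")


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criterion for the amide N-H donor.

    Relaxed distance/angle thresholds: donor-acceptor N...O distance at most
    ``max_da_dist`` and D-H...A angle at least ``min_dha_angle``.
    """

    max_da_dist: float = 3.5    # Angstrom
    min_dha_angle: float = 120.0  # degrees


@dataclass(frozen=True)
class DenaturantSeries:
    """DeltaG_ex (kcal/mol) measured at increasing denaturant concentrations (M)."""

    residue_key: tuple
    concentrations: tuple[float, ...]
    dg_ex: tuple[float, ...]

    def __post_init__(self):
        c = np.asarray(self.concentrations, float)
        if len(c) != len(self.dg_ex):
            raise ValueError("concentrations and dg_ex must have equal length")
        if len(c) >= 2 and not np.all(np.diff(c) > 0):
            raise ValueError("concentrations must be strictly increasing")


# ---------------------------------------------------------------------------
# Burial
# ---------------------------------------------------------------------------

def compute_burial(structure: ProteinStructure,
                   residue_key: tuple[str, int] | tuple[str, int, str],
                   radius: float = 6.5,
                   scope: str = "all-atoms",
                   include_het: bool = False) -> int:
    """Heavy-atom contact count around the amide nitrogen.

    Counts non-hydrogen atoms with Euclidean distance <= ``radius`` from the
    residue's backbone N, excluding that N itself.  ``scope="backbone-only"``
    restricts the counted atoms to N/CA/C/O; waters and hetero atoms are
    excluded unless ``include_het``.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if scope not in ("all-atoms", "backbone-only"):
        raise ValueError("scope must be 'all-atoms' or 'backbone-only'")
    chain, res_seq, icode = _norm_key(residue_key)
    n_atom = structure.get_atom(chain, res_seq, "N", icode)
    if n_atom is None:
        raise FeatureUnavailableError(
            f"residue {chain}/{res_seq}{icode} has no backbone N atom")
    center = n_atom.pos
    count = 0
    for a in structure.atoms:
        if a is n_atom:
            continue
        if a.is_hydrogen:
            continue
        if (a.het or a.is_water) and not include_het:
            continue
        if scope == "backbone-only" and a.name not in BACKBONE_NAMES:
            continue
        d = a.pos - center
        if float(d @ d) <= radius * radius:
            count += 1
    return count


def _norm_key(key) -> tuple[str, int, str]:
    if len(key) == 2:
        return (key[0], key[1], "")
    return (key[0], key[1], key[2])


# ---------------------------------------------------------------------------
# Secondary structure
# ---------------------------------------------------------------------------

_SS_KIND_TO_CATEGORY = {
    "alpha-helix": "helix",
    "3/10-helix": "helix",
    "pi-helix": "helix",   # closest of the three model categories
    "strand": "beta-sheet",
    "bridge": "beta-sheet",
}


def ss_category(structure: ProteinStructure,
                residue_key: tuple[str, int] | tuple[str, int, str]) -> str:
    """Secondary-structure category of a residue from HELIX/SHEET spans."""
    chain, res_seq, _ = _norm_key(residue_key)
    for span in structure.ss_spans:
        if span.contains(chain, res_seq):
            return _SS_KIND_TO_CATEGORY[span.kind]
    return "no"


# ---------------------------------------------------------------------------
# Hydrogen bonding
# ---------------------------------------------------------------------------

def _amide_hydrogen(structure: ProteinStructure, chain: str, res_seq: int,
                    icode: str, n_atom: Atom) -> np.ndarray | None:
    """Position of the amide H: from the file if present, else built from
    backbone geometry (in the C(i-1)-N-CA plane, opposite the bisector)."""
    for name in ("H", "HN", "D"):
        h = structure.get_atom(chain, res_seq, name, icode)
        if h is not None:
            return h.pos
    ca = structure.get_atom(chain, res_seq, "CA", icode)
    # preceding residue's carbonyl C; author numbering is assumed contiguous
    c_prev = structure.get_atom(chain, res_seq - 1, "C", icode)
    if ca is None or c_prev is None:
        return None
    u = n_atom.pos - ca.pos
    v = n_atom.pos - c_prev.pos
    u /= np.linalg.norm(u)
    v /= np.linalg.norm(v)
    d = u + v
    norm = np.linalg.norm(d)
    if norm < 1e-8:
        return None
    return n_atom.pos + 1.01 * d / norm


def _acceptor_class(atom: Atom) -> str | None:
    """Classify an O acceptor: water, main-chain or side-chain oxygen."""
    if atom.element != "O":
        return None
    if atom.is_water:
        return "Hbond-with-H2O"
    if atom.name in ("O", "OXT"):
        return "Hbond-with-mainchain-O"
    return "Hbond-with-sidechain-O"


#: main-chain > side-chain > water, matching the dominance of main-chain
#: acceptors in folded proteins
_HBOND_PRECEDENCE = ("Hbond-with-mainchain-O", "Hbond-with-sidechain-O",
                     "Hbond-with-H2O")


def hbond_category(structure: ProteinStructure,
                   residue_key: tuple[str, int] | tuple[str, int, str],
                   criteria: HBondCriteria = HBondCriteria(),
                   ) -> tuple[str, int]:
    """Hydrogen-bond category and acceptor count ``N_i^H`` for one amide.

    Applies the geometric criterion of ``criteria`` with the amide N-H as
    donor against all O acceptors (backbone, side-chain, water), excluding
    the covalently adjacent oxygens of the residue itself and of the
    preceding residue's carbonyl.  When several acceptors qualify the
    category is chosen by precedence main-chain > side-chain > water and the
    count reports all qualifying acceptors.
    """
    chain, res_seq, icode = _norm_key(residue_key)
    n_atom = structure.get_atom(chain, res_seq, "N", icode)
    if n_atom is None:
        raise FeatureUnavailableError(
            f"residue {chain}/{res_seq}{icode} has no backbone N atom")
    h_pos = _amide_hydrogen(structure, chain, res_seq, icode, n_atom)
    found: list[str] = []
    for a in structure.atoms:
        cls = _acceptor_class(a)
        if cls is None:
            continue
        # exclude covalent neighbourhood: own residue O, previous residue's C=O
        if a.residue_key == (chain, res_seq, icode):
            continue
        if a.residue_key == (chain, res_seq - 1, icode) and a.name in ("O", "OXT"):
            continue
        da = np.linalg.norm(a.pos - n_atom.pos)
        if da > criteria.max_da_dist:
            continue
        if h_pos is not None:
            hv1 = n_atom.pos - h_pos
            hv2 = a.pos - h_pos
            cosang = (hv1 @ hv2) / (np.linalg.norm(hv1) * np.linalg.norm(hv2))
            angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            if angle < criteria.min_dha_angle:
                continue
        found.append(cls)
    if not found:
        return ("no", 0)
    for cat in _HBOND_PRECEDENCE:
        if cat in found:
            return (cat, len(found))
    return ("no", 0)  # unreachable


# ---------------------------------------------------------------------------
# HX-enabling motion classification
# ---------------------------------------------------------------------------

def classify_motion(series: DenaturantSeries,
                    slope_threshold: float = 0.5,
                    curvature_alpha: float = 0.05) -> str:
    """Classify the HX-enabling motion from DeltaG_ex vs denaturant.

    A flat dependence (|slope| below ``slope_threshold`` kcal/mol/M) means
    exchange through local fluctuations (``L``); a significantly non-linear
    dependence (quadratic lack-of-fit at level ``curvature_alpha``) means
    partial unfolding (``UD``); a strong linear dependence means global
    unfolding (``UD+EX1``).
    """
    c = np.asarray(series.concentrations, float)
    g = np.asarray(series.dg_ex, float)
    if len(c) < 3:
        raise ValueError("motion classification needs at least 3 points")
    X = sm.add_constant(c)
    lin = sm.OLS(g, X).fit()
    slope = float(lin.params[1])
    if abs(slope) < slope_threshold:
        return "L"
    if len(c) >= 4:
        Xq = np.column_stack([np.ones_like(c), c, c * c])
        quad = sm.OLS(g, Xq).fit()
        p_quad = float(quad.pvalues[2])
        if np.isfinite(p_quad) and p_quad < curvature_alpha:
            return "UD"
    else:
        # 3 points determine a quadratic exactly; fall back to a relative
        # curvature criterion
        coef = np.polyfit(c, g, 2)
        if abs(coef[0]) * (c[-1] - c[0]) > slope_threshold:
            return "UD"
    return "UD+EX1"


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def build_features(structure: ProteinStructure,
                   annotations,
                   radius: float = 6.5,
                   scope: str = "all-atoms",
                   include_het: bool = False,
                   criteria: HBondCriteria = HBondCriteria(),
                   ) -> list[ResidueFeatures]:
    """Assemble one :class:`ResidueFeatures` per annotated residue.

    ``annotations`` is an annotation-table DataFrame (see
    :mod:`poppet.structure_io`).  Precomputed ``burial`` / ``hbond_category``
    / ``motion_category`` columns override structure-derived values.
    Prolines and the first residue of each chain are flagged non-exchanging.
    """
    from .structure_io import AA3_TO_1, validate_annotation_table

    validate_annotation_table(annotations)
    known = {(k[0], k[1]) for k in structure.residues(include_het=True)}
    first_per_chain: dict[str, int] = {}
    for ch, rs, _ in structure.residues():
        first_per_chain.setdefault(ch, rs)
        first_per_chain[ch] = min(first_per_chain[ch], rs)

    unmatched = []
    out: list[ResidueFeatures] = []
    for row in annotations.itertuples(index=False):
        chain, res = str(row.chain), int(row.residue)
        if (chain, res) not in known:
            unmatched.append(f"{chain}/{res}")
            continue
        res_name = structure.residue_name(chain, res) or "UNK"
        aa = getattr(row, "aa", None)
        if not isinstance(aa, str) or not aa:
            aa = AA3_TO_1.get(res_name, "X")
        burial = getattr(row, "burial", None)
        if burial is None or (isinstance(burial, float) and np.isnan(burial)):
            burial = compute_burial(structure, (chain, res), radius=radius,
                                    scope=scope, include_het=include_het)
        hb = getattr(row, "hbond_category", None)
        if isinstance(hb, str) and hb:
            hb_count = 1 if hb != "no" else 0
        else:
            hb, hb_count = hbond_category(structure, (chain, res), criteria)
        motion = getattr(row, "motion_category", None)
        if not isinstance(motion, str) or not motion:
            motion = None
        exchanging = aa != "P" and res != first_per_chain.get(chain, res - 1)
        out.append(ResidueFeatures(
            chain=chain, residue=res, aa=aa, burial=int(burial),
            ss=ss_category(structure, (chain, res)),
            hbond=hb, hbond_count=int(hb_count), motion=motion,
            exchanging=exchanging))
    if unmatched:
        raise KeyError(
            "annotation residues absent from the structure: "
            + ", ".join(unmatched))
    return out
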