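"""Structure and table I/O.

Reads PDB files (coordinates plus HELIX/SHEET secondary-structure records)
into a light-weight :class:`ProteinStructure`, reads/writes the CSV
interchange tables used throughout the pipeline (per-residue annotations,
protection-factor tables, peptide definitions), and generates deterministic
synthetic structures for testing.

Conventions
-----------
* Residues are addressed by *author* numbering, i.e. the numbers printed in
  the PDB file, together with the insertion code.  This matches HELIX/SHEET
  records and published supplementary tables.
* Only MODEL 1 of multi-model files is used.
* For alternate locations the highest-occupancy atom is kept (ties broken
  in favour of altloc 'A').
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "Atom",
    "SSSpan",
    "ProteinStructure",
    "PeptideDef",
    "StructureFormatError",
    "EmptyStructureError",
    "TableSchemaError",
    "MOTION_CATEGORIES",
    "HBOND_CATEGORIES",
    "SS_CATEGORIES",
    "read_pdb",
    "read_annotation_table",
    "write_annotation_table",
    "read_pf_table",
    "write_pf_table",
    "read_peptides",
    "write_peptides",
    "make_synthetic_structure",
]

#: Closed set of HX-enabling motion categories: local fluctuations (L),
#: unfolding detected via denaturant (UD), via elevated pH (EX1), or both.
MOTION_CATEGORIES = ("L", "UD", "EX1", "UD+EX1")

#: Hydrogen-bond acceptor categories for the amide N-H donor.
HBOND_CATEGORIES = (
    "no",
    "Hbond-with-H2O",
    "Hbond-with-mainchain-O",
    "Hbond-with-sidechain-O",
)

#: Secondary-structure categories (alpha- and 3/10-helices collapse to
#: "helix"; strands and bridges to "beta-sheet").
SS_CATEGORIES = ("no", "helix", "beta-sheet")

#: Secondary-structure span kinds as parsed from HELIX/SHEET records.
SS_KINDS = ("alpha-helix", "3/10-helix", "pi-helix", "strand", "bridge")

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "D2O", "H2O"})


class StructureFormatError(ValueError):
    """The file could not be parsed as PDB."""


class EmptyStructureError(ValueError):
    """The file contains no ATOM records."""


class TableSchemaError(ValueError):
    """A CSV table is missing required columns or violates an invariant."""


@dataclass(frozen=True)
class Atom:
    chain: str
    res_seq: int
    icode: str          # insertion code, '' if none
    res_name: str       # 3-letter
    name: str           # atom name, stripped
    element: str        # upper-case element symbol, never empty
    x: float
    y: float
    z: float
    het: bool = False
    altloc: str = ""
    occupancy: float = 1.0

    @property
    def pos(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain, self.res_seq, self.icode)

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    @property
    def is_water(self) -> bool:
        return self.res_name in WATER_NAMES


@dataclass(frozen=True)
class SSSpan:
    chain: str
    start: int
    end: int
    kind: str  # one of SS_KINDS

    def __post_init__(self):
        if self.kind not in SS_KINDS:
            raise ValueError(f"unknown SS kind {self.kind!r}; valid: {SS_KINDS}")

    def contains(self, chain: str, res_seq: int) -> bool:
        return chain == self.chain and self.start <= res_seq <= self.end


@dataclass
class ProteinStructure:
    """Atoms of one conformer plus secondary-structure spans."""

    atoms: list[Atom] = field(default_factory=list)
    ss_spans: list[SSSpan] = field(default_factory=list)

    def __post_init__(self):
        for a in self.atoms:
            if not np.isfinite([a.x, a.y, a.z]).all():
                raise ValueError(f"non-finite coordinates for atom {a}")
            if not a.element:
                raise ValueError(f"empty element symbol for atom {a}")

    # -- residue-level accessors -------------------------------------------
    def residues(self, chain: str | None = None,
                 include_het: bool = False) -> list[tuple[str, int, str]]:
        """Ordered unique residue keys (chain, res_seq, icode)."""
        seen: dict[tuple[str, int, str], None] = {}
        for a in self.atoms:
            if a.het and not include_het:
                continue
            seen.setdefault(a.residue_key, None)
        if chain is not None:
            return [k for k in seen if k[0] == chain]
        return list(seen)

    def residue_atoms(self, chain: str, res_seq: int,
                      icode: str = "") -> list[Atom]:
        key = (chain, res_seq, icode)
        return [a for a in self.atoms if a.residue_key == key]

    def get_atom(self, chain: str, res_seq: int, name: str,
                 icode: str = "") -> Atom | None:
        for a in self.atoms:
            if a.residue_key == (chain, res_seq, icode) and a.name == name:
                return a
        return None

    def residue_name(self, chain: str, res_seq: int, icode: str = "") -> str | None:
        for a in self.atoms:
            if a.residue_key == (chain, res_seq, icode):
                return a.res_name
        return None

    def transformed(self, rotation: np.ndarray,
                    translation: np.ndarray) -> "ProteinStructure":
        """Rigid-body transform (used by invariance tests)."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        new = []
        for a in self.atoms:
            p = R @ a.pos + t
            new.append(replace(a, x=float(p[0]), y=float(p[1]), z=float(p[2])))
        return ProteinStructure(atoms=new, ss_spans=list(self.ss_spans))


# ---------------------------------------------------------------------------
# PDB reading (gemmi-backed)
# ---------------------------------------------------------------------------

_HELIX_KIND = {
    "RAlpha": "alpha-helix",
    "LAlpha": "alpha-helix",
    "R310": "3/10-helix",
    "RPi": "pi-helix",
    "LPi": "pi-helix",
}


def read_pdb(path: str | Path) -> ProteinStructure:
    """Read a PDB file into a :class:`ProteinStructure`.

    Only MODEL 1 is used; alternate locations are collapsed to the
    highest-occupancy atom (ties -> altloc 'A'); elements are inferred from
    atom names when columns 77-78 are absent.  HELIX/SHEET records populate
    ``ss_spans`` (a warning is emitted when none are present).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()  # ensures element inference / het flags are set
    if len(st) == 0:
        raise EmptyStructureError(f"{path} contains no ATOM records")

    model = st[0]  # MODEL 1 only
    atoms: list[Atom] = []
    # collapse altlocs: key -> best Atom
    best: dict[tuple, Atom] = {}
    order: list[tuple] = []
    for chain in model:
        for res in chain:
            het = res.het_flag == "H"
            for at in res:
                altloc = at.altloc if at.altloc and at.altloc != "\x00" else ""
                element = at.element.name.upper()
                if not element or element == "X":
                    raise StructureFormatError(
                        f"cannot infer element for atom {at.name!r} in "
                        f"{chain.name}/{res.seqid.num}")
                atom = Atom(
                    chain=chain.name,
                    res_seq=res.seqid.num,
                    icode=res.seqid.icode.strip(),
                    res_name=res.name,
                    name=at.name,
                    element=element,
                    x=at.pos.x, y=at.pos.y, z=at.pos.z,
                    het=het,
                    altloc=altloc,
                    occupancy=at.occ,
                )
                key = atom.residue_key + (atom.name,)
                prev = best.get(key)
                if prev is None:
                    best[key] = atom
                    order.append(key)
                else:
                    # keep highest occupancy; ties -> lexicographically
                    # smallest altloc ('A' beats 'B')
                    if (atom.occupancy, prev.altloc or "~") > \
                       (prev.occupancy, atom.altloc or "~"):
                        best[key] = atom
    atoms = [best[k] for k in order]
    if not any(not a.het for a in atoms):
        raise EmptyStructureError(f"{path} contains no ATOM records")

    spans: list[SSSpan] = []
    for h in st.helices:
        kind = _HELIX_KIND.get(h.pdb_helix_class.name, "alpha-helix")
        spans.append(SSSpan(chain=h.start.chain_name,
                            start=h.start.res_id.seqid.num,
                            end=h.end.res_id.seqid.num, kind=kind))
    for sheet in st.sheets:
        for strand in sheet.strands:
            spans.append(SSSpan(chain=strand.start.chain_name,
                                start=strand.start.res_id.seqid.num,
                                end=strand.end.res_id.seqid.num,
                                kind="strand"))
    if not spans:
        warnings.warn(f"{path}: no HELIX/SHEET records; all residues will "
                      "fall in secondary-structure category 'no'")
    return ProteinStructure(atoms=atoms, ss_spans=spans)


# ---------------------------------------------------------------------------
# CSV interchange tables
# ---------------------------------------------------------------------------

ANNOTATION_REQUIRED = ("chain", "residue")
ANNOTATION_OPTIONAL = ("aa", "logpf_measured", "motion_category",
                       "burial", "hbond_category", "set_label")
PF_REQUIRED = ("chain", "residue", "logpf")
PEPTIDE_REQUIRED = ("peptide_id", "chain", "start", "end", "sequence")


def _require_columns(df: pd.DataFrame, required: Sequence[str], kind: str):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableSchemaError(
            f"{kind} table is missing required column(s): {', '.join(missing)}")


def _check_unique_residue(df: pd.DataFrame, kind: str):
    dup = df.duplicated(subset=["chain", "residue"])
    if dup.any():
        keys = df.loc[dup, ["chain", "residue"]].itertuples(index=False)
        raise TableSchemaError(
            f"duplicate (chain, residue) in {kind} table: "
            + ", ".join(f"{c}/{r}" for c, r in keys))


def validate_annotation_table(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, ANNOTATION_REQUIRED, "annotation")
    _check_unique_residue(df, "annotation")
    if "motion_category" in df.columns:
        cats = df["motion_category"].dropna()
        bad = sorted(set(cats) - set(MOTION_CATEGORIES))
        if bad:
            raise TableSchemaError(
                f"invalid motion category {bad}; valid categories: "
                f"{list(MOTION_CATEGORIES)}")
    if "hbond_category" in df.columns:
        cats = df["hbond_category"].dropna()
        bad = sorted(set(cats) - set(HBOND_CATEGORIES))
        if bad:
            raise TableSchemaError(
                f"invalid H-bond category {bad}; valid categories: "
                f"{list(HBOND_CATEGORIES)}")
    if "logpf_measured" in df.columns:
        vals = pd.to_numeric(df["logpf_measured"], errors="coerce")
        present = df["logpf_measured"].notna()
        if (present & ~np.isfinite(vals.where(present, 0.0))).any():
            raise TableSchemaError("non-finite logpf_measured values")
    return df


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return validate_annotation_table(df)


def write_annotation_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_annotation_table(df)
    df.to_csv(path, index=False)


def read_pf_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, PF_REQUIRED, "protection-factor")
    _check_unique_residue(df, "protection-factor")
    return df


def write_pf_table(df: pd.DataFrame, path: str | Path) -> None:
    _require_columns(df, PF_REQUIRED, "protection-factor")
    _check_unique_residue(df, "protection-factor")
    df.to_csv(path, index=False)


@dataclass(frozen=True)
class PeptideDef:
    """A proteolytic peptide: contiguous residue span plus its sequence."""

    peptide_id: str
    chain: str
    start: int
    end: int
    sequence: str  # 1-letter, length == end - start + 1

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(
                f"peptide {self.peptide_id}: start {self.start} > end {self.end}")
        n = self.end - self.start + 1
        if len(self.sequence) != n:
            raise ValueError(
                f"peptide {self.peptide_id}: sequence length "
                f"{len(self.sequence)} != span length {n}")

    @property
    def residues(self) -> list[int]:
        return list(range(self.start, self.end + 1))


def read_peptides(path: str | Path) -> list[PeptideDef]:
    df = pd.read_csv(path)
    _require_columns(df, PEPTIDE_REQUIRED, "peptide")
    return [
        PeptideDef(str(r.peptide_id), str(r.chain), int(r.start), int(r.end),
                   str(r.sequence))
        for r in df.itertuples(index=False)
    ]


def write_peptides(peptides: Iterable[PeptideDef], path: str | Path) -> None:
    df = pd.DataFrame(
        [(p.peptide_id, p.chain, p.start, p.end, p.sequence) for p in peptides],
        columns=list(PEPTIDE_REQUIRED))
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Synthetic structures
# ---------------------------------------------------------------------------

# Ideal backbone internal coordinates (Engh & Huber averages).
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_A_CA_C_O = 120.8


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension-reference-frame placement of atom d."""
    ang = np.deg2rad(angle_deg)
    tor = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([-bond * np.cos(ang),
                   bond * np.sin(ang) * np.cos(tor),
                   bond * np.sin(ang) * np.sin(tor)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _backbone_chain(n_residues: int, phi: float, psi: float,
                    omega: float = 180.0) -> list[dict[str, np.ndarray]]:
    """Backbone N/CA/C/O coordinates for an ideal (phi, psi) repeat."""
    # seed the first three atoms
    coords: list[dict[str, np.ndarray]] = []
    N = np.array([0.0, 0.0, 0.0])
    CA = N + np.array([_B_N_CA, 0.0, 0.0])
    ang = np.deg2rad(180.0 - _A_N_CA_C)
    C = CA + _B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    res = {"N": N, "CA": CA, "C": C}
    coords.append(res)
    for _ in range(1, n_residues):
        prev = coords[-1]
        Nn = _place(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi)
        CAn = _place(prev["CA"], prev["C"], Nn, _B_N_CA, _A_C_N_CA, omega)
        Cn = _place(prev["C"], Nn, CAn, _B_CA_C, _A_N_CA_C, phi)
        coords.append({"N": Nn, "CA": CAn, "C": Cn})
    # carbonyl O in the peptide plane, anti to the next N
    for i, res in enumerate(coords):
        if i + 1 < len(coords):
            nxt = coords[i + 1]["N"]
            res["O"] = _place(nxt, res["CA"], res["C"], _B_C_O,
                              _A_CA_C_O, 180.0)
        else:
            res["O"] = _place(res["N"], res["CA"], res["C"], _B_C_O,
                              _A_CA_C_O, psi + 180.0)
    return coords


def make_synthetic_structure(kind: str, n_residues: int = 10, seed: int = 0,
                             chain: str = "A",
                             distances: Sequence[float] | None = None,
                             elements: Sequence[str] | None = None,
                             ) -> ProteinStructure:
    """Deterministic synthetic structures for tests and examples.

    Parameters
    ----------
    kind
        ``"ideal-helix"`` — poly-Ala backbone with canonical alpha-helix
        geometry (1.5 A rise, 100 deg/residue) so the i -> i-4 hydrogen bond
        geometry holds, annotated with a matching HELIX span;
        ``"ideal-strand"`` — extended beta conformation with a SHEET span;
        ``"point-cloud"`` — a probe backbone N at the origin surrounded by
        carbon atoms at the caller-specified ``distances`` (random
        directions drawn from ``seed``).
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    rng = np.random.default_rng(seed)

    if kind == "point-cloud":
        atoms = [Atom(chain, 1, "", "ALA", "N", "N", 0.0, 0.0, 0.0)]
        elements = elements or ["C"] * len(distances or [])
        for i, (d, el) in enumerate(zip(distances or [], elements)):
            v = rng.normal(size=3)
            v *= float(d) / np.linalg.norm(v)
            name = "H" if el.upper() in ("H", "D") else el.upper()
            atoms.append(Atom(chain, 2 + i, "", "ALA", name, el.upper(),
                              float(v[0]), float(v[1]), float(v[2])))
        return ProteinStructure(atoms=atoms, ss_spans=[])

    if kind == "ideal-helix":
        phi, psi = -57.8, -47.0
        span_kind = "alpha-helix"
    elif kind == "ideal-strand":
        phi, psi = -139.0, 135.0
        span_kind = "strand"
    else:
        raise ValueError(f"unknown synthetic structure kind {kind!r}")

    bb = _backbone_chain(n_residues, phi, psi)
    atoms = []
    for i, res in enumerate(bb, start=1):
        for name in ("N", "CA", "C", "O"):
            p = res[name]
            atoms.append(Atom(chain, i, "", "ALA", name, name[0],
                              float(p[0]), float(p[1]), float(p[2])))
    spans = [SSSpan(chain=chain, start=1, end=n_residues, kind=span_kind)]
    return ProteinStructure(atoms=atoms, ss_spans=spans)
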