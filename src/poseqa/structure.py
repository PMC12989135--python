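"""Parsing, cleaning and role annotation of immunoglobulin-antigen complexes.

Structures arrive as PDB or mmCIF files with one or more immunoglobulin-side
chains (antibody heavy/light, nanobody, scFv, TCR alpha/beta) bound to one or
more antigen-side chains (monomeric antigen, MHC, peptide).  Parsing is
delegated to gemmi; this module owns the cleaning rules (HETATM / non-standard
residue removal, altloc resolution by highest summed occupancy) and the
chain-role vocabulary that downstream featurization consumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np

STANDARD_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

IG_ROLES = {"ig_heavy", "ig_light", "nanobody", "scfv", "tcr_alpha", "tcr_beta"}
AG_ROLES = {"antigen", "mhc", "peptide"}
ALL_ROLES = IG_ROLES | AG_ROLES


class StructureError(ValueError):
    """Raised for unparseable, empty or inconsistently annotated structures."""


@dataclass
class AtomRecord:
    name: str
    element: str
    coord: np.ndarray  # (3,) Angstrom
    occupancy: float = 1.0
    altloc: str = ""
    is_hetatm: bool = False

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise StructureError(f"atom {self.name}: coordinate must be 3 finite floats")
        if not 0.0 <= self.occupancy <= 1.0:
            raise StructureError(f"atom {self.name}: occupancy {self.occupancy} outside [0,1]")


@dataclass
class Residue:
    name3: str
    seq_id: int          # author residue number
    icode: str = ""      # insertion code, "" if none
    atoms: list = field(default_factory=list)
    is_hetatm: bool = False

    @property
    def key(self) -> str:
        return f"{self.seq_id}{self.icode}"

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_coords(self) -> np.ndarray:
        coords = [a.coord for a in self.atoms if a.element.upper() != "H"]
        if not coords:  # hydrogen-only residue: fall back to everything
            coords = [a.coord for a in self.atoms]
        return np.asarray(coords)

    def one_letter(self) -> str:
        return AA3_TO_1.get(self.name3, "X")


@dataclass
class ComplexStructure:
    chains: dict  # chain id -> list[Residue], insertion-ordered
    source_id: str = ""

    @property
    def n_residues(self) -> int:
        return sum(len(v) for v in self.chains.values())

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for v in self.chains.values() for r in v)


@dataclass
class ChainAnnotation:
    chain_id: str
    role: str
    cdr_intervals: list = field(default_factory=list)  # [(start,end)] inclusive, author numbers

    def __post_init__(self):
        if self.role not in ALL_ROLES:
            raise StructureError(f"chain {self.chain_id}: unknown role {self.role!r}")
        if self.cdr_intervals and self.side != "ig":
            raise StructureError(f"chain {self.chain_id}: CDR intervals on antigen-side chain")

    @property
    def side(self) -> str:
        return "ig" if self.role in IG_ROLES else "ag"


@dataclass
class TypedComplex:
    structure: ComplexStructure
    annotations: list  # list[ChainAnnotation]

    def annotation(self, chain_id: str) -> ChainAnnotation:
        for a in self.annotations:
            if a.chain_id == chain_id:
                return a
        raise KeyError(chain_id)

    def side_chains(self, side: str) -> list:
        return [a.chain_id for a in self.annotations if a.side == side]


# ---------------------------------------------------------------------------
# parsing

def parse_structure(path, fmt: str = "auto") -> ComplexStructure:
    """Read a PDB or mmCIF file into a ComplexStructure.

    All ATOM/HETATM records of the first model are captured with altloc and
    occupancy preserved; residues stay grouped per chain in file order.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    coor = {"pdb": gemmi.CoorFormat.Pdb,
            "mmcif": gemmi.CoorFormat.Mmcif,
            "auto": gemmi.CoorFormat.Detect}[fmt]
    try:
        st = gemmi.read_structure(str(path), format=coor)
    except (RuntimeError, ValueError) as e:
        raise StructureError(f"cannot parse {path}: {e}") from e
    if len(st) == 0:
        raise StructureError(f"{path}: no atoms (empty model)")
    model = st[0]
    chains: dict = {}
    for chain in model:
        residues = []
        for res in chain:
            rec = Residue(
                name3=res.name,
                seq_id=res.seqid.num,
                icode=res.seqid.icode.strip(),
                is_hetatm=(res.het_flag == "H"),
            )
            for atom in res:
                rec.atoms.append(AtomRecord(
                    name=atom.name,
                    element=atom.element.name,
                    coord=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    occupancy=min(max(atom.occ, 0.0), 1.0),
                    altloc=atom.altloc.strip() if atom.altloc != "\x00" else "",
                    is_hetatm=(res.het_flag == "H"),
                ))
            if rec.atoms:
                residues.append(rec)
        if residues:
            chains[chain.name] = residues
    if not chains:
        raise StructureError(f"{path}: no atoms")
    return ComplexStructure(chains=chains, source_id=path.stem)


# ---------------------------------------------------------------------------
# cleaning

def _resolve_altlocs(res: Residue) -> Residue:
    labels = sorted({a.altloc for a in res.atoms if a.altloc},
                    key=lambda l: next(i for i, a in enumerate(res.atoms) if a.altloc == l))
    if not labels:
        return res
    # keep the altloc set with the highest summed occupancy; tie -> first in file order
    best = max(labels, key=lambda l: (sum(a.occupancy for a in res.atoms if a.altloc == l),
                                      -labels.index(l)))
    kept = [replace(a, altloc="") for a in res.atoms if a.altloc in ("", best)]
    return replace(res, atoms=kept)


def clean_structure(s: ComplexStructure) -> ComplexStructure:
    """Drop HETATM / non-standard residues and resolve alternative locations.

    A residue is removed if its name is not one of the 20 standard amino-acid
    codes or if it was read from HETATM records (waters, glycans, MSE and
    other modified residues are dropped, not converted).  For residues with
    altlocs only the label with the highest summed occupancy is retained and
    the altloc flags are cleared.  Chains emptied by cleaning are dropped.
    """
    chains: dict = {}
    for cid, residues in s.chains.items():
        kept = []
        for res in residues:
            if res.is_hetatm or res.name3 not in STANDARD_AA3:
                continue
            res = _resolve_altlocs(res)
            if res.atoms:
                kept.append(replace(res, is_hetatm=False))
        if kept:
            chains[cid] = kept
    if not chains:
        raise StructureError(f"{s.source_id}: no standard residues after cleaning")
    return ComplexStructure(chains=chains, source_id=s.source_id)


# ---------------------------------------------------------------------------
# role annotation

def assign_roles(s: ComplexStructure, annotations) -> TypedComplex:
    """Attach chain roles and CDR intervals, validating coverage and sides."""
    anns = [a if isinstance(a, ChainAnnotation) else ChainAnnotation(**a) for a in annotations]
    by_id = {a.chain_id: a for a in anns}
    missing = [cid for cid in s.chains if cid not in by_id]
    if missing:
        raise StructureError(f"unannotated chains: {', '.join(missing)}")
    anns = [by_id[cid] for cid in s.chains]  # structure order, drop extraneous rows
    sides = {a.side for a in anns}
    if sides != {"ig", "ag"}:
        raise StructureError("all chains on one side: no interface possible")
    for a in anns:
        keys = {r.seq_id for r in s.chains[a.chain_id]}
        for start, end in a.cdr_intervals:
            if start > end or not any(start <= k <= end for k in keys):
                raise StructureError(
                    f"chain {a.chain_id}: CDR interval {start}-{end} outside chain")
    return TypedComplex(structure=s, annotations=anns)


def read_annotations(path) -> list:
    """Read chain annotations from TSV (chain_id, role, cdr_intervals) or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
        return [ChainAnnotation(chain_id=r["chain_id"], role=r["role"],
                                cdr_intervals=[tuple(iv) for iv in r.get("cdr_intervals", [])])
                for r in rows]
    anns = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("chain_id"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise StructureError(f"{path}: malformed annotation line {line!r}")
        cid, role = parts[0], parts[1]
        intervals = []
        if len(parts) > 2 and parts[2].strip():
            for span in parts[2].split(";"):
                try:
                    start, end = span.split("-")
                    intervals.append((int(start), int(end)))
                except ValueError as e:
                    raise StructureError(f"{path}: bad CDR interval {span!r}") from e
        anns.append(ChainAnnotation(chain_id=cid, role=role, cdr_intervals=intervals))
    return anns


def write_annotations(anns, path) -> None:
    lines = ["chain_id\trole\tcdr_intervals"]
    for a in anns:
        spans = ";".join(f"{s}-{e}" for s, e in a.cdr_intervals)
        lines.append(f"{a.chain_id}\t{a.role}\t{spans}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# writing

def write_pdb(s: ComplexStructure, path) -> None:
    """Write a (cleaned) structure as a standard PDB file via gemmi."""
    st = gemmi.Structure()
    st.name = s.source_id or "complex"
    model = gemmi.Model("1")
    for cid, residues in s.chains.items():
        chain = gemmi.Chain(cid)
        for res in residues:
            gres = gemmi.Residue()
            gres.name = res.name3
            gres.seqid = gemmi.SeqId(res.seq_id, res.icode or " ")
            gres.het_flag = "H" if res.is_hetatm else "A"
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.coord)
                ga.occ = a.occupancy
                if a.altloc:
                    ga.altloc = a.altloc
                gres.add_atom(ga)
            chain.add_residue(gres)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
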