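"""Structure data model, PDB I/O, geometry queries and formal-charge
accounting.

The in-memory model is deliberately small: a :class:`Structure` is an ordered
list of :class:`Residue` objects holding :class:`Atom` records, plus a
registry of covalent links (pairs of atom serials, e.g. the glycosyl-enzyme
ester bond).  Coordinates are stored in Å exactly as read from the PDB file;
no recentering or symmetry expansion is performed.  Substrate atoms are the
HETATM records.

Protonation is handled by bookkeeping only: :class:`ProtonationRules` maps
residue names to formal-charge contributions under the standard convention
(Asp/Glu −1, Lys/Arg +1, His neutral ε-tautomer, zwitterionic termini) and
the total formal charge of a structure is the sum of those contributions plus
any declared hetero-group charge.  No hydrogen placement or pKa prediction is
attempted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from .errors import SelectionError, StructureError, UnknownResidueError

logger = logging.getLogger(__name__)

#: The 20 canonical amino acids, 3-letter -> 1-letter.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
CANONICAL_AA = frozenset(THREE_TO_ONE)


@dataclass
class Atom:
    """A single atom record."""

    serial: int
    name: str
    element: str
    coords: np.ndarray  # shape (3,), Å
    is_substrate: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.serial}: coords must be a finite 3-vector")
        if not self.element:
            raise StructureError(f"atom {self.serial}: empty element symbol")

    def copy(self) -> "Atom":
        return replace(self, coords=self.coords.copy())


@dataclass
class Residue:
    chain: str
    seq_number: int
    res_name: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""

    def __post_init__(self) -> None:
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            raise StructureError(
                f"residue {self.res_name} {self.chain}{self.seq_number}: duplicate atom names"
            )

    @property
    def is_hetero(self) -> bool:
        return self.res_name not in CANONICAL_AA

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.seq_number, self.insertion_code)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise SelectionError(
            f"no atom {name!r} in residue {self.res_name} {self.chain}{self.seq_number}"
        )

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def copy(self) -> "Residue":
        return Residue(
            chain=self.chain,
            seq_number=self.seq_number,
            res_name=self.res_name,
            atoms=[a.copy() for a in self.atoms],
            insertion_code=self.insertion_code,
        )


@dataclass
class Selector:
    """Addresses a unique atom either by (chain, seq_number, atom_name) or,
    for hetero groups, by (res_name, atom_name)."""

    atom_name: str
    chain: str | None = None
    seq_number: int | None = None
    res_name: str | None = None

    def resolve(self, s: "Structure") -> Atom:
        hits = []
        for res in s.residues:
            if self.chain is not None and res.chain != self.chain:
                continue
            if self.seq_number is not None and res.seq_number != self.seq_number:
                continue
            if self.res_name is not None and res.res_name != self.res_name:
                continue
            for a in res.atoms:
                if a.name == self.atom_name:
                    hits.append(a)
        if len(hits) != 1:
            raise SelectionError(f"selector {self} resolved to {len(hits)} atoms (need exactly 1)")
        return hits[0]


@dataclass
class Structure:
    """An ordered residue list plus a covalent-link registry.

    ``links`` holds unordered pairs of atom serials (from CONECT records or
    from derivation steps); ``state_tag`` labels the mechanistic state the
    coordinates represent: the enzyme–substrate complex (``ES``), the covalent
    glycosyl-enzyme intermediate (``GE``) or an interpolation ``frame``.
    """

    residues: list[Residue] = field(default_factory=list)
    links: set[frozenset[int]] = field(default_factory=set)
    state_tag: str = "ES"

    def __post_init__(self) -> None:
        if self.n_atoms == 0:
            raise StructureError("structure has no atoms")
        serials = [a.serial for a in self.atoms()]
        if len(serials) != len(set(serials)):
            raise StructureError("duplicate atom serials")
        known = set(serials)
        for link in self.links:
            if not link <= known:
                raise StructureError(f"link {set(link)} references unknown atom serial")

    # -- iteration / lookup -------------------------------------------------
    def atoms(self):
        for res in self.residues:
            yield from res.atoms

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def atom_by_serial(self, serial: int) -> Atom:
        for a in self.atoms():
            if a.serial == serial:
                return a
        raise SelectionError(f"no atom with serial {serial}")

    def residue_of(self, atom: Atom) -> Residue:
        for res in self.residues:
            if atom in res.atoms:
                return res
        raise SelectionError(f"atom serial {atom.serial} not in any residue")

    def substrate_atoms(self) -> list[Atom]:
        return [a for a in self.atoms() if a.is_substrate]

    def protein_residues(self) -> list[Residue]:
        return [r for r in self.residues if not r.is_hetero]

    def coords_matrix(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms()], dtype=float)

    def max_serial(self) -> int:
        return max(a.serial for a in self.atoms())

    def atom_key(self, atom: Atom) -> tuple:
        res = self.residue_of(atom)
        return (res.chain, res.seq_number, res.insertion_code, atom.name)

    def atom_by_key(self, key: tuple) -> Atom:
        chain, seq, icode, name = key
        for res in self.residues:
            if res.key == (chain, seq, icode):
                return res.atom(name)
        raise SelectionError(f"no residue with key {key[:3]}")

    def link_keys(self) -> set[frozenset[tuple]]:
        """Links expressed as pairs of (chain, seq, icode, name) keys —
        stable across re-serialization."""
        by_serial = {a.serial: self.atom_key(a) for a in self.atoms()}
        return {frozenset(by_serial[s] for s in link) for link in self.links}

    def are_linked(self, a: Atom, b: Atom) -> bool:
        return frozenset((a.serial, b.serial)) in self.links

    def copy(self) -> "Structure":
        return Structure(
            residues=[r.copy() for r in self.residues],
            links=set(self.links),
            state_tag=self.state_tag,
        )


# -- geometry ---------------------------------------------------------------

def distance(s: Structure, a: Selector | Atom, b: Selector | Atom) -> float:
    """Euclidean distance in Å between two uniquely resolved atoms."""
    atom_a = a.resolve(s) if isinstance(a, Selector) else a
    atom_b = b.resolve(s) if isinstance(b, Selector) else b
    return float(np.linalg.norm(atom_a.coords - atom_b.coords))


def residues_within(s: Structure, center: list[Atom], r: float) -> list[Residue]:
    """Residues with at least one atom within ``r`` Å of any center atom.

    Substrate (hetero) residues are excluded from the result; inclusion uses
    the minimum over all (residue atom, center atom) pairs, ``<= r``.
    """
    if not center:
        raise SelectionError("residues_within: empty center atom set")
    if r < 0:
        raise ValueError("radius must be non-negative")
    cpts = np.array([a.coords for a in center])
    out = []
    for res in s.residues:
        if res.is_hetero or any(a.is_substrate for a in res.atoms):
            continue
        pts = np.array([a.coords for a in res.atoms])
        d2 = ((pts[:, None, :] - cpts[None, :, :]) ** 2).sum(axis=2)
        dmin = float(np.sqrt(d2.min()))
        if dmin <= r:
            out.append(res)
    return out


# -- protonation / formal charge -------------------------------------------

#: Standard formal-charge contributions at physiological pH.
STANDARD_CHARGES = {
    "ASP": -1, "GLU": -1, "LYS": +1, "ARG": +1,
    "HIS": 0, "CYS": 0, "TYR": 0, "SER": 0, "THR": 0,
}


@dataclass
class ProtonationRules:
    """Residue-name -> formal charge map plus terminus handling.

    Zwitterionic termini contribute +1 (N-terminus) and −1 (C-terminus) per
    chain.  Hetero groups must appear in ``hetero_charges``; anything else
    unknown raises.
    """

    charges: dict[str, int] = field(default_factory=lambda: dict(STANDARD_CHARGES))
    n_terminus: int = +1
    c_terminus: int = -1
    hetero_charges: dict[str, int] = field(default_factory=dict)

    def residue_charge(self, res_name: str) -> int:
        if res_name in self.charges:
            return self.charges[res_name]
        if res_name in CANONICAL_AA:
            return 0
        if res_name in self.hetero_charges:
            return self.hetero_charges[res_name]
        raise UnknownResidueError(
            f"residue {res_name!r} not covered by protonation rules and has no declared charge"
        )


def formal_charge(s: Structure, rules: ProtonationRules) -> int:
    """Total formal charge under the given protonation convention.

    Sum of per-residue contributions, plus zwitterionic terminus charges for
    every protein chain, plus declared hetero-group charges.
    """
    total = 0
    chains = set()
    for res in s.residues:
        total += rules.residue_charge(res.res_name)
        if not res.is_hetero:
            chains.add(res.chain)
    total += len(chains) * (rules.n_terminus + rules.c_terminus)
    return total


# -- PDB I/O ----------------------------------------------------------------

def read_pdb(path) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    ATOM records become protein residues, HETATM records are flagged as
    substrate, CONECT records populate the link registry.  Alternate
    locations other than 'A'/blank are dropped with a warning.
    """
    path = str(path)
    try:
        st = gemmi.read_structure(path, format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, OSError, ValueError) as exc:
        raise StructureError(f"cannot read PDB file {path}: {exc}") from exc

    residues: list[Residue] = []
    dropped_alt = 0
    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    model = st[0]
    for chain in model:
        for res in chain:
            atoms = []
            for at in res:
                if at.altloc not in ("", "\0", "A"):
                    dropped_alt += 1
                    continue
                atoms.append(
                    Atom(
                        serial=at.serial,
                        name=at.name,
                        element=at.element.name or at.name[0],
                        coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        is_substrate=(res.het_flag == "H" and res.name != "HOH"),
                    )
                )
            if atoms:
                residues.append(
                    Residue(
                        chain=chain.name,
                        seq_number=res.seqid.num,
                        res_name=res.name,
                        atoms=atoms,
                        insertion_code=(res.seqid.icode or "").strip(),
                    )
                )
    if dropped_alt:
        warnings.warn(f"{path}: dropped {dropped_alt} alternate-location atoms (kept 'A'/blank)")
    if not residues:
        raise StructureError(f"{path}: no ATOM/HETATM records")

    links: set[frozenset[int]] = set()
    known = {a.serial for r in residues for a in r.atoms}
    with open(path) as fh:
        for line in fh:
            if line.startswith("CONECT"):
                fields = [line[i:i + 5].strip() for i in range(6, len(line.rstrip()), 5)]
                serials = [int(f) for f in fields if f]
                if len(serials) >= 2:
                    base = serials[0]
                    for other in serials[1:]:
                        if base in known and other in known and base != other:
                            links.add(frozenset((base, other)))
    return Structure(residues=residues, links=links)


def write_pdb(s: Structure, path) -> None:
    """Write a Structure as PDB (ATOM/HETATM/TER/CONECT, %8.3f coordinates)."""
    with open(str(path), "w") as fh:
        fh.write(format_pdb(s))


def format_pdb(s: Structure) -> str:
    lines = []
    prev_chain = None
    for res in s.residues:
        if prev_chain is not None and res.chain != prev_chain:
            lines.append("TER")
        prev_chain = res.chain
        record = "HETATM" if res.is_hetero else "ATOM  "
        for a in res.atoms:
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            lines.append(
                f"{record}{a.serial:>5d} {name:<4s} {res.res_name:<3s} {res.chain:1s}"
                f"{res.seq_number:>4d}{res.insertion_code or ' ':1s}   "
                f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
                f"  1.00  0.00          {a.element:>2s}"
            )
    for link in sorted(s.links, key=lambda l: tuple(sorted(l))):
        i, j = sorted(link)
        lines.append(f"CONECT{i:>5d}{j:>5d}")
        lines.append(f"CONECT{j:>5d}{i:>5d}")
    lines.append("END")
    return "\n".join(lines) + "\n"
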