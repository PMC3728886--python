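"""Deterministic toy systems and ground-truth surfaces.

The toy system is a miniature analog of a glycoside-hydrolase active site:
a two-fragment substrate (a sugar-like fragment carrying the anomeric carbon
C1 and a nitrophenol-like leaving group carrying the phenolic oxygen O1), a
glutamate-like nucleophile residue whose carboxylate oxygen OE1 defines the
reaction coordinate together with C1, and a shell of alanine residues placed
at controlled radii so that the distance-based active-site rule selects a
known subset.  Chemical realism is deliberately sacrificed for verifiable
geometry: residues are small rigid groups, and the energetics come from the
programmable surrogate surface, not from the coordinates.

Everything is a pure function of the spec (including its seed): the same
spec yields bit-identical structures.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import GenerationError
from .pathway import ReactionCoordinate
from .structure import Atom, ProtonationRules, Residue, Selector, Structure
from .surrogate import SurrogateSurface

#: angular positions use a golden-angle spiral for even spacing
GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


@dataclass(frozen=True)
class ToySystemSpec:
    n_residues: int = 8          # protein residues incl. the nucleophile
    n_active: int = 3            # residues inside the 4 Å shell (incl. nucleophile)
    substrate_sizes: tuple[int, int] = (3, 3)
    seed: int = 7
    clash_positions: frozenset[int] = frozenset()   # seq numbers walled in
    active_radius: float = 4.0
    x1_es: float = 3.0
    x1_ge: float = 1.5

    def __post_init__(self):
        if self.n_active > self.n_residues:
            raise GenerationError("n_active cannot exceed n_residues")
        if self.n_active < 1:
            raise GenerationError("need at least the nucleophile inside the shell")


@dataclass(frozen=True)
class GroundTruth:
    """Programmed barriers the pipeline must recover."""

    wt_barrier: float = 18.5
    mutant_barriers: dict = field(default_factory=dict)   # label -> kcal/mol
    additive: bool = True
    charge_mismatch_labels: frozenset[str] = frozenset()
    lewis_failure_labels: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.wt_barrier < 0 or any(b < 0 for b in self.mutant_barriers.values()):
            raise ValueError("barriers must be non-negative")


@dataclass
class ToySystem:
    es: Structure
    ge: Structure
    rc: ReactionCoordinate
    phenolic: Selector
    ground_truth: GroundTruth
    rules: ProtonationRules


def _ala_residue(chain: str, seq: int, origin: np.ndarray, radial: np.ndarray,
                 tangent: np.ndarray, serial_start: int) -> Residue:
    """A rigid alanine placed so its N atom is the closest atom to the
    substrate (at ``origin``) and the side chain grows tangentially, leaving
    open space for mutant side chains."""
    normal = np.cross(radial, tangent)
    coords = {
        "N": origin,
        "CA": origin + 1.46 * tangent,
        "C": origin + 1.46 * tangent + 1.52 * (0.5 * radial + 0.87 * normal),
        "O": origin + 1.46 * tangent + 1.52 * (0.5 * radial + 0.87 * normal) + 1.23 * radial,
        "CB": origin + 2.99 * tangent,
    }
    atoms = [
        Atom(serial=serial_start + i, name=name, element=name[0], coords=xyz)
        for i, (name, xyz) in enumerate(coords.items())
    ]
    return Residue(chain=chain, seq_number=seq, res_name="ALA", atoms=atoms)


def _wall_residue(chain: str, seq: int, target: Residue, serial_start: int) -> Residue:
    """A ring of blocker atoms on the circle swept by a CG atom around the
    CA→CB axis of ``target``, guaranteeing a sub-1.5 Å contact for any side
    chain extending beyond CB."""
    ca = target.atom("CA").coords
    cb = target.atom("CB").coords
    axis = cb - ca
    axis /= np.linalg.norm(axis)
    helper = np.array([0.0, 0.0, 1.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    # CG sits ~1.52 Å from CB at ~111° from the CA direction
    axial = 1.52 * math.cos(math.radians(69.0))
    r_circ = 1.52 * math.sin(math.radians(69.0))
    center = cb + axial * axis
    atoms = []
    for i in range(8):
        phi = 2 * math.pi * i / 8
        xyz = center + r_circ * (math.cos(phi) * e1 + math.sin(phi) * e2)
        atoms.append(Atom(serial=serial_start + i, name=f"X{i+1}", element="C",
                          coords=xyz, is_substrate=False))
    return Residue(chain=chain, seq_number=seq, res_name="WAL", atoms=atoms)


def make_toy_system(spec: ToySystemSpec, ground_truth: GroundTruth | None = None) -> ToySystem:
    """Correspondence-matched ES and GE structures plus the reaction
    coordinate and programmed ground truth.

    The two states differ only in the substrate fragment positions: in GE the
    anomeric carbon is covalently linked to the nucleophile oxygen at
    ``x1_ge``; in ES it sits at ``x1_es`` with the leaving group re-attached.
    """
    gt = ground_truth or GroundTruth()

    oe1 = np.array([-spec.x1_ge, 0.0, 0.0])
    c1_ge = np.zeros(3)
    c1_es = np.array([spec.x1_es - spec.x1_ge, 0.0, 0.0])

    def substrate_residues(state: str, serial_start: int) -> list[Residue]:
        n_sugar, n_leave = spec.substrate_sizes
        if n_sugar < 1 or n_leave < 1:
            raise GenerationError("substrate fragments need at least one atom each")
        sugar_offsets = [np.zeros(3)] + [
            np.array([0.4 * i, 1.1 + 0.3 * i, 0.5 * ((-1) ** i)]) for i in range(1, n_sugar)
        ]
        c1 = c1_ge if state == "GE" else c1_es
        sugar_atoms = [
            Atom(serial=serial_start + i,
                 name="C1" if i == 0 else f"C{i+1}",
                 element="C", coords=c1 + off, is_substrate=True)
            for i, off in enumerate(sugar_offsets)
        ]
        # leaving group: detached in GE, bonded at the glycosidic length in ES
        if state == "GE":
            o1 = c1_ge + np.array([3.0, 0.0, 0.0])
        else:
            o1 = c1_es + np.array([1.43, 0.0, 0.0])
        leave_offsets = [np.zeros(3)] + [
            np.array([1.2 * i, 0.3 * i, -0.4 * ((-1) ** i)]) for i in range(1, n_leave)
        ]
        leave_atoms = [
            Atom(serial=serial_start + n_sugar + i,
                 name="O1" if i == 0 else f"C{i+10}",
                 element="O" if i == 0 else "C", coords=o1 + off, is_substrate=True)
            for i, off in enumerate(leave_offsets)
        ]
        return [
            Residue(chain="S", seq_number=901, res_name="XYL", atoms=sugar_atoms),
            Residue(chain="S", seq_number=902, res_name="ONP", atoms=leave_atoms),
        ]

    def nucleophile(serial_start: int) -> Residue:
        base = oe1 + np.array([-1.0, 0.8, 0.0])
        coords = {
            "N": base + np.array([-2.8, 1.2, 0.6]),
            "CA": base + np.array([-2.4, 0.6, -0.6]),
            "C": base + np.array([-3.2, -0.4, -1.2]),
            "O": base + np.array([-4.2, -0.7, -0.7]),
            "CB": base + np.array([-1.2, 0.0, -0.3]),
            "CG": base + np.array([-0.6, 0.6, 0.6]),
            "CD": base + np.array([0.4, 0.0, 1.0]),
            "OE1": oe1,
            "OE2": base + np.array([1.2, 0.8, 1.6]),
        }
        atoms = [Atom(serial=serial_start + i, name=n, element=n[0], coords=xyz)
                 for i, (n, xyz) in enumerate(coords.items())]
        return Residue(chain="A", seq_number=1, res_name="GLU", atoms=atoms)

    def build(state: str, angle_jitter: np.ndarray) -> Structure:
        residues: list[Residue] = []
        serial = 1
        nuc = nucleophile(serial)
        serial += len(nuc.atoms)
        residues.append(nuc)

        # substrate anchor for shell distances: midpoint of the C1 travel
        anchor = 0.5 * (c1_ge + c1_es)
        n_shell = spec.n_residues - 1
        n_active_shell = spec.n_active - 1
        walls: list[Residue] = []
        for i in range(n_shell):
            # golden-angle spiral in the plane orthogonal to the reaction axis,
            # tilted deterministically by the seed
            theta = GOLDEN_ANGLE * (i + 1) + 0.1 * angle_jitter[i]
            u = np.array([0.15 * math.sin(theta * 2.0),
                          math.cos(theta), math.sin(theta)])
            u /= np.linalg.norm(u)
            if i < n_active_shell:
                radius = 3.2 + 0.2 * (i % 3)   # nearest atom well inside 4 Å
            else:
                radius = 7.0 + 2.5 * (i - n_active_shell)
            origin = anchor + radius * u
            tangent = np.cross(u, np.array([1.0, 0.0, 0.0]))
            tangent /= np.linalg.norm(tangent)
            seq = 10 + i
            res = _ala_residue("A", seq, origin, u, tangent, serial)
            serial += len(res.atoms)
            residues.append(res)
            if seq in spec.clash_positions:
                wall = _wall_residue("A", 800 + i, res, serial)
                serial += len(wall.atoms)
                walls.append(wall)
        residues.extend(walls)
        subs = substrate_residues(state, serial)
        residues.extend(subs)

        links = set()
        c1_serial = subs[0].atom("C1").serial
        o1_serial = subs[1].atom("O1").serial
        oe1_serial = nuc.atom("OE1").serial
        if state == "GE":
            links.add(frozenset((oe1_serial, c1_serial)))
        else:
            links.add(frozenset((c1_serial, o1_serial)))
        return Structure(residues=residues, links=links, state_tag=state)

    rc = ReactionCoordinate(
        atom_a=Selector(atom_name="OE1", chain="A", seq_number=1),
        atom_b=Selector(atom_name="C1", res_name="XYL"),
    )
    phenolic = Selector(atom_name="O1", res_name="ONP")

    from .mutants import detect_active_site
    from .pathway import DEFAULT_DMIN, close_contact_check

    def acceptable(st: Structure) -> bool:
        # the 4 A rule must select exactly n_active protein residues, and no
        # non-bonded pair may start below the close-contact rejection radius
        if len(detect_active_site(st, spec.active_radius)) != spec.n_active:
            return False
        ok, _ = close_contact_check(st, DEFAULT_DMIN)
        return ok

    # deterministic retry over derived jitter seeds: the golden-angle spiral
    # plus jitter can occasionally push a shell atom onto the substrate, so
    # jittered placements are screened until a clean one appears.  Each
    # attempt draws one jitter value per shell residue, shared by the ES and
    # GE builds so the two states stay bit-identical outside the substrate.
    es = ge = None
    for attempt in range(50):
        rng = np.random.default_rng(spec.seed + 9973 * attempt)
        angle_jitter = rng.standard_normal(max(spec.n_residues - 1, 1))
        ge_try = build("GE", angle_jitter)
        es_try = build("ES", angle_jitter)
        if acceptable(ge_try) and acceptable(es_try):
            ge, es = ge_try, es_try
            break
    if ge is None:
        raise GenerationError(
            f"placement infeasible: no clean geometry with exactly "
            f"{spec.n_active} active residues found for seed {spec.seed}"
        )

    rules = ProtonationRules(hetero_charges={"XYL": 0, "ONP": -1, "WAL": 0})
    return ToySystem(es=es, ge=ge, rc=rc, phenolic=phenolic, ground_truth=gt, rules=rules)


def make_surface(
    gt: GroundTruth,
    noise_sd: float = 0.0,
    seed: int = 0,
    x1_es: float = 3.0,
    x1_ge: float = 1.5,
    reortho_sd: float = 0.0,
) -> SurrogateSurface:
    """Surrogate surface whose analytic barrier equals the programmed ground
    truth per mutant (exactly, when noise_sd = 0)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    offsets = {label: b - gt.wt_barrier for label, b in gt.mutant_barriers.items()}
    return SurrogateSurface(
        x1_es=x1_es, x1_ge=x1_ge,
        barrier_height=gt.wt_barrier,
        mutant_offsets=offsets,
        noise_sd=noise_sd, noise_seed=seed,
        reortho_sd=reortho_sd,
        charge_mismatch_labels=gt.charge_mismatch_labels,
        lewis_failure_labels=gt.lewis_failure_labels,
    )


def export_fixture(system: ToySystem, directory) -> None:
    """Write the toy system as PDB files plus a JSON ground-truth sidecar."""
    import os

    from .structure import write_pdb

    os.makedirs(str(directory), exist_ok=True)
    write_pdb(system.es, os.path.join(str(directory), "toy_es.pdb"))
    write_pdb(system.ge, os.path.join(str(directory), "toy_ge.pdb"))
    sidecar = {
        "wt_barrier": system.ground_truth.wt_barrier,
        "mutant_barriers": dict(system.ground_truth.mutant_barriers),
        "additive": system.ground_truth.additive,
        "reaction_coordinate": {
            "atom_a": {"chain": "A", "seq_number": 1, "atom_name": "OE1"},
            "atom_b": {"res_name": "XYL", "atom_name": "C1"},
        },
    }
    with open(os.path.join(str(directory), "ground_truth.json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)
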