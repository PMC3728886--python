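"""Structure-derivation pathways, Cartesian constraint sets and constrained
linear interpolation along the reaction coordinate.

The rate-limiting glycosylation step is bracketed by two stationary points:
the enzyme–substrate complex (ES) and the covalent glycosyl-enzyme
intermediate (GE).  The reaction coordinate x1 is the distance between the
nucleophile carboxylate oxygen and the anomeric carbon of the proximal sugar
unit.  A reaction profile is mapped by freezing x1 to a ladder of values
between its ES and GE endpoints while everything inside an optimization layer
relaxes; coordinates of residues outside the layer are frozen to their values
in the previously optimized origin structure.

Five derivation pathways are supported.  Pathways 1–2 prepare wild-type
endpoints (pathway 2 re-derives ES from the optimized GE, which is cheaper
and better behaved); pathways 3–5 prepare mutant endpoints, with pathway 5 —
mutate the GE, then transplant the non-covalent substrate pose — the
recommended production route.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    ConfigurationError,
    CorrespondenceError,
    DerivationError,
    SelectionError,
)
from .structure import Atom, Residue, Selector, Structure, distance, residues_within

logger = logging.getLogger(__name__)

#: standard glycosidic C–O bond length used when re-forming the substrate bond
GLYCOSIDIC_BOND = 1.43

#: default close-contact rejection threshold (Å)
DEFAULT_DMIN = 0.7

X1_TOLERANCE = 1e-6


@dataclass
class ReactionCoordinate:
    """The constrained distance x1 between two uniquely addressed atoms
    (nucleophile O^epsilon and anomeric carbon C1)."""

    atom_a: Selector
    atom_b: Selector

    def measure(self, s: Structure) -> float:
        return distance(s, self.atom_a, self.atom_b)

    def serials(self, s: Structure) -> tuple[int, int]:
        return (self.atom_a.resolve(s).serial, self.atom_b.resolve(s).serial)


@dataclass(frozen=True)
class ConstraintSet:
    """Cartesian freezing of all atoms in residues beyond a layer radius of
    the active site.  Reaction-coordinate atoms are never members."""

    fixed_serials: frozenset[int]
    layer_radius: float
    origin_state: str = "GE"

    def __len__(self) -> int:
        return len(self.fixed_serials)


EMPTY_CONSTRAINTS = ConstraintSet(frozenset(), float("inf"))


@dataclass
class Frame:
    """One interpolation point: a geometry whose x1 is pinned to a target."""

    structure: Structure
    x1_target: float
    constraint: ConstraintSet
    index: int


@dataclass
class PathwayPlan:
    pathway_id: int
    steps: list[str] = field(default_factory=list)
    uses_constraints: bool = False


def derive_es_from_ge(
    ge: Structure,
    rc: ReactionCoordinate,
    phenolic: Selector,
    bond_length: float = GLYCOSIDIC_BOND,
) -> Structure:
    """Form the enzyme–substrate complex from a glycosyl-enzyme intermediate.

    Breaks the covalent nucleophile–C1 ester link, re-forms the glycosidic
    C1–O(phenolic) bond and rigid-body translates the leaving-group fragment
    (the residue containing the phenolic oxygen) so the new bond has the
    standard glycosidic length, directed along the former nucleophile→C1
    axis.  All other coordinates are untouched.
    """
    atom_a = rc.atom_a.resolve(ge)
    atom_b = rc.atom_b.resolve(ge)
    if not ge.are_linked(atom_a, atom_b):
        raise DerivationError(
            "derive_es_from_ge: no covalent link between the nucleophile oxygen and C1 "
            "(structure is not a GE state, or derivation was already applied)"
        )
    try:
        ophen = phenolic.resolve(ge)
    except SelectionError as exc:
        raise DerivationError(f"derive_es_from_ge: leaving-group fragment missing ({exc})") from exc
    if ge.are_linked(ophen, atom_b):
        raise DerivationError("derive_es_from_ge: C1 already bonded to the phenolic oxygen")

    out = ge.copy()
    a = out.atom_by_serial(atom_a.serial)
    b = out.atom_by_serial(atom_b.serial)
    o = out.atom_by_serial(ophen.serial)

    out.links.discard(frozenset((a.serial, b.serial)))
    out.links.add(frozenset((b.serial, o.serial)))

    direction = b.coords - a.coords
    direction /= np.linalg.norm(direction)
    new_o = b.coords + bond_length * direction
    shift = new_o - o.coords
    fragment = out.residue_of(o)
    for atom in fragment.atoms:
        atom.coords = atom.coords + shift
    out.state_tag = "ES"
    return out


def extract_and_modify_substrate(mut_ge: Structure, wt_es_prime: Structure) -> Structure:
    """Build a mutant ES by transplanting the non-covalent substrate pose.

    Protein coordinates come from the (optimized) mutant GE; substrate
    coordinates come from the wild-type ES'; the link registry becomes that
    of an ES state (all links that touch the substrate are taken from ES').
    Substrate atoms are matched by (chain, seq, insertion code, atom name).
    """
    ge_sub = {mut_ge.atom_key(a): a for a in mut_ge.substrate_atoms()}
    es_sub = {wt_es_prime.atom_key(a): a for a in wt_es_prime.substrate_atoms()}
    if set(ge_sub) != set(es_sub):
        missing = set(ge_sub) ^ set(es_sub)
        raise CorrespondenceError(
            f"substrate atom naming mismatch between GE and ES' ({sorted(missing)[:4]} ...)"
        )

    out = mut_ge.copy()
    for key, src in es_sub.items():
        out.atom_by_key(key).coords = src.coords.copy()

    # link registry of an ES state: protein-protein links from the mutant GE,
    # substrate-involving links from ES'
    sub_serials_ge = {a.serial for a in out.substrate_atoms()}
    protein_links = {l for l in out.links if not (l & sub_serials_ge)}
    substrate_link_keys = {
        pair for pair in wt_es_prime.link_keys()
        if any(k in es_sub for k in pair)
    }
    new_links = set(protein_links)
    for pair in substrate_link_keys:
        try:
            serials = frozenset(out.atom_by_key(k).serial for k in pair)
        except SelectionError as exc:
            raise CorrespondenceError(f"ES' link endpoint missing in mutant GE: {exc}") from exc
        new_links.add(serials)
    out.links = new_links
    out.state_tag = "ES"
    return out


def build_constraints(
    s: Structure,
    active_center: list[Atom],
    layer_radius: float,
    rc: ReactionCoordinate | None = None,
) -> ConstraintSet:
    """Freeze every atom of residues with no atom within ``layer_radius`` of
    the active center.

    An infinite radius gives an empty fixed set (unconstrained).  Substrate
    residues are always mobile.  Reaction-coordinate atoms are removed from
    the fixed set with a warning if a fixed residue happens to contain one.
    """
    if not active_center:
        raise SelectionError("build_constraints: empty active center")
    if not (layer_radius > 0):
        raise ValueError("layer_radius must be positive (or infinite)")
    if np.isinf(layer_radius):
        return ConstraintSet(frozenset(), layer_radius, s.state_tag)

    mobile = {res.key for res in residues_within(s, active_center, layer_radius)}
    fixed = set()
    for res in s.residues:
        if res.is_hetero or any(a.is_substrate for a in res.atoms):
            continue
        if res.key not in mobile:
            fixed.update(a.serial for a in res.atoms)
    if rc is not None:
        for serial in rc.serials(s):
            if serial in fixed:
                logger.warning(
                    "reaction-coordinate atom %d was inside the fixed layer; unfreezing it",
                    serial,
                )
                fixed.discard(serial)
    return ConstraintSet(frozenset(fixed), layer_radius, s.state_tag)


def _correspondence_keys(s: Structure) -> list[tuple]:
    return [s.atom_key(a) for a in s.atoms()]


def make_frames(
    es: Structure,
    ge: Structure,
    rc: ReactionCoordinate,
    n_intermediate: int = 10,
    constraints: ConstraintSet | None = None,
) -> list[Frame]:
    """Linear interpolation frames from ES to GE.

    Produces ``n_intermediate + 2`` frames indexed 0..n+1 with frame 0 the ES
    endpoint and the last frame the GE endpoint.  Intermediate coordinates
    are the linear blend ``(1 - t_k) * ES + t_k * GE`` with ``t_k = k/(n+1)``;
    the x1 target of each frame is enforced exactly (to 1e-6 Å) by rescaling
    the C1 atom position along the nucleophile→C1 axis.  If a constraint set
    is given, fixed atoms take their coordinates verbatim from the origin
    endpoint so they are bit-identical across all frames.
    """
    keys_es = _correspondence_keys(es)
    keys_ge = _correspondence_keys(ge)
    if keys_es != keys_ge:
        raise CorrespondenceError(
            f"ES/GE atom correspondence mismatch ({len(keys_es)} vs {len(keys_ge)} atoms "
            "or differing names/order)"
        )
    x1_es = rc.measure(es)
    x1_ge = rc.measure(ge)
    if abs(x1_es - x1_ge) < 1e-9:
        raise DerivationError("degenerate path: x1 identical at both endpoints")

    serial_a = rc.atom_a.resolve(es).serial
    serial_b = rc.atom_b.resolve(es).serial
    coords_es = es.coords_matrix()
    coords_ge = ge.coords_matrix()
    origin = ge if (constraints is None or constraints.origin_state == "GE") else es
    coords_origin = origin.coords_matrix()
    fixed = constraints.fixed_serials if constraints is not None else frozenset()
    serial_order = [a.serial for a in es.atoms()]
    serial_index = {ser: i for i, ser in enumerate(serial_order)}

    n_total = n_intermediate + 2
    frames: list[Frame] = []
    cset = constraints if constraints is not None else EMPTY_CONSTRAINTS
    for k in range(n_total):
        t = k / (n_total - 1)
        target = (1.0 - t) * x1_es + t * x1_ge
        if k == 0:
            st = es.copy()
        elif k == n_total - 1:
            st = ge.copy()
        else:
            st = es.copy()
            blended = (1.0 - t) * coords_es + t * coords_ge
            for ser in fixed:
                blended[serial_index[ser]] = coords_origin[serial_index[ser]]
            # enforce the x1 target exactly by moving C1 along the a→b axis
            pa = blended[serial_index[serial_a]]
            pb = blended[serial_index[serial_b]]
            axis = pb - pa
            norm = np.linalg.norm(axis)
            blended[serial_index[serial_b]] = pa + axis * (target / norm)
            for atom, xyz in zip(st.atoms(), blended):
                atom.coords = xyz
        st.state_tag = "frame"
        frames.append(Frame(structure=st, x1_target=target, constraint=cset, index=k))
        achieved = rc.measure(st)
        if abs(achieved - target) > X1_TOLERANCE:
            raise DerivationError(
                f"frame {k}: x1 {achieved:.8f} deviates from target {target:.8f}"
            )
    return frames


def close_contact_check(
    f: Frame | Structure, dmin: float = DEFAULT_DMIN
) -> tuple[bool, list[tuple[int, int, float]]]:
    """Scan for non-bonded atom pairs closer than ``dmin`` Å.

    Pairs joined by a registered covalent link, or belonging to the same
    residue, are exempt.  Returns (passed, offending_pairs) where each
    offending pair is (serial_i, serial_j, distance).
    """
    if dmin <= 0:
        raise ValueError("dmin must be positive")
    s = f.structure if isinstance(f, Frame) else f
    atoms = list(s.atoms())
    coords = np.array([a.coords for a in atoms])
    res_of = {}
    for ridx, res in enumerate(s.residues):
        for a in res.atoms:
            res_of[a.serial] = ridx
    tree = cKDTree(coords)
    offending = []
    for i, j in sorted(tree.query_pairs(dmin)):
        ai, aj = atoms[i], atoms[j]
        if res_of[ai.serial] == res_of[aj.serial]:
            continue
        if s.are_linked(ai, aj):
            continue
        d = float(np.linalg.norm(ai.coords - aj.coords))
        offending.append((ai.serial, aj.serial, d))
    return (len(offending) == 0, offending)


#: executable step sequences for the five derivation pathways
_PATHWAY_STEPS = {
    1: ["modify substrate (1): WT GE -> WT ES", "optimize WT ES", "optimize WT GE",
        "interpolate ES -> GE"],
    2: ["optimize WT GE", "modify substrate (2): WT GE opt -> WT ES'",
        "define constraints K", "apply constraints K", "optimize WT ES'",
        "interpolate ES' -> GE"],
    3: ["mutate WT ES opt -> Mut ES", "mutate WT GE opt -> Mut GE",
        "optimize Mut ES", "optimize Mut GE", "interpolate ES -> GE"],
    4: ["mutate WT ES' -> Mut ES'", "optimize Mut ES'",
        "mutate WT GE opt -> Mut GE", "optimize Mut GE", "interpolate ES' -> GE"],
    5: ["mutate WT GE opt -> Mut GE", "optimize Mut GE", "extract substrate",
        "modify substrate (3): transplant WT ES' substrate -> Mut ES''",
        "optimize Mut ES''", "interpolate ES'' -> GE"],
}

_PATHWAY_PRECURSORS = {
    1: {"wt_ge"},
    2: {"wt_ge_opt"},
    3: {"wt_es_opt", "wt_ge_opt"},
    4: {"wt_es_prime_opt", "wt_ge_opt"},
    5: {"wt_ge_opt", "wt_es_prime_opt"},
}


def plan_pathway(
    pathway_id: int,
    wt_structures: dict[str, Structure],
    mutation=None,
    use_constraints: bool = False,
) -> PathwayPlan:
    """Ordered executable step list for a derivation pathway.

    Pathways 1–2 are wild-type only; 3–5 require a mutation.  Pathway 3
    cannot use constraints: its two endpoints are modelled independently, so
    frozen outer-layer coordinates would disagree between them.
    """
    if pathway_id not in _PATHWAY_STEPS:
        raise ConfigurationError(f"unknown pathway {pathway_id}")
    if pathway_id in (1, 2) and mutation is not None:
        raise ConfigurationError(f"pathway {pathway_id} is wild-type only")
    if pathway_id in (3, 4, 5) and mutation is None:
        raise ConfigurationError(f"pathway {pathway_id} requires a mutation")
    if pathway_id == 3 and use_constraints:
        raise ConfigurationError("constraints cannot be applied in pathway 3")
    missing = _PATHWAY_PRECURSORS[pathway_id] - set(wt_structures)
    if missing:
        raise ConfigurationError(
            f"pathway {pathway_id} requires precursor structures {sorted(missing)}"
        )
    return PathwayPlan(
        pathway_id=pathway_id,
        steps=list(_PATHWAY_STEPS[pathway_id]),
        uses_constraints=use_constraints,
    )


# -- frame serialization ------------------------------------------------------

def write_frames(frames: list[Frame], pdb_path, sidecar_path=None) -> None:
    """Serialize frames as a multi-model PDB plus a JSON sidecar with the
    per-frame x1 targets and constraint membership."""
    import json

    from .structure import format_pdb

    with open(str(pdb_path), "w") as fh:
        for frame in frames:
            fh.write(f"MODEL     {frame.index + 1:>4d}\n")
            body = format_pdb(frame.structure)
            fh.write(body.replace("END\n", ""))
            fh.write("ENDMDL\n")
        fh.write("END\n")
    if sidecar_path is not None:
        meta = [
            {
                "index": f.index,
                "x1_target": f.x1_target,
                "fixed_serials": sorted(f.constraint.fixed_serials),
                "layer_radius": f.constraint.layer_radius,
            }
            for f in frames
        ]
        with open(str(sidecar_path), "w") as fh:
            json.dump(meta, fh, indent=1, default=float)
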