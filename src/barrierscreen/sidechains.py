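"""Side-chain templates and deterministic chi-angle placement.

Side chains are rebuilt from ideal internal coordinates (bond lengths, bond
angles, dihedrals) using the standard NeRF construction.  Rotatable chi
dihedrals are searched on a fixed 30-degree grid (exhaustive over
combinations, up to chi4) against a hard-sphere clash score, followed by a
finer deterministic refinement of the best combination.  This replaces
interactive mutagenesis tools with a reproducible, scriptable equivalent.

Only heavy atoms are modelled; hydrogens are left to the downstream energy
engine, which is the convention for semiempirical whole-protein input decks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

# hard-sphere van der Waals radii (Å), scaled by CLASH_SCALE in the score
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "H": 1.20}
DEFAULT_VDW = 1.70
CLASH_SCALE = 0.8

#: minimum allowed non-bonded contact after relaxation; below this the mutant
#: is flagged un-buildable (mirrors discarding sterically impossible Pro/Tyr).
MIN_CONTACT = 1.5

CHI_GRID_STEP = 30.0  # degrees
REFINE_SPAN = 15.0
REFINE_STEP = 5.0


@dataclass(frozen=True)
class TemplateAtom:
    """One side-chain atom defined in internal coordinates.

    ``dihedral`` is either ``("chi", k, offset_deg)`` — the atom's dihedral is
    the k-th rotatable chi plus a fixed offset — or ``("fixed", deg)``.
    ``refs`` are the names of the three previously placed atoms: bonded
    parent, angle partner, dihedral partner.
    """

    name: str
    element: str
    refs: tuple[str, str, str]
    bond: float
    angle: float
    dihedral: tuple


def _t(name, element, refs, bond, angle, dihedral):
    return TemplateAtom(name, element, tuple(refs), bond, angle, tuple(dihedral))


def _chain(*entries):
    return tuple(entries)


#: ideal side-chain geometry beyond CB for all 20 canonical amino acids
SIDE_CHAIN_TEMPLATES: dict[str, tuple[TemplateAtom, ...]] = {
    "GLY": _chain(),
    "ALA": _chain(),
    "SER": _chain(_t("OG", "O", ("CB", "CA", "N"), 1.42, 110.5, ("chi", 1, 0.0))),
    "CYS": _chain(_t("SG", "S", ("CB", "CA", "N"), 1.81, 114.0, ("chi", 1, 0.0))),
    "THR": _chain(
        _t("OG1", "O", ("CB", "CA", "N"), 1.43, 109.5, ("chi", 1, 0.0)),
        _t("CG2", "C", ("CB", "CA", "N"), 1.52, 110.5, ("chi", 1, -120.0)),
    ),
    "VAL": _chain(
        _t("CG1", "C", ("CB", "CA", "N"), 1.52, 110.5, ("chi", 1, 0.0)),
        _t("CG2", "C", ("CB", "CA", "N"), 1.52, 110.5, ("chi", 1, 120.0)),
    ),
    "LEU": _chain(
        _t("CG", "C", ("CB", "CA", "N"), 1.53, 116.3, ("chi", 1, 0.0)),
        _t("CD1", "C", ("CG", "CB", "CA"), 1.52, 110.5, ("chi", 2, 0.0)),
        _t("CD2", "C", ("CG", "CB", "CA"), 1.52, 110.5, ("chi", 2, 120.0)),
    ),
    "ILE": _chain(
        _t("CG1", "C", ("CB", "CA", "N"), 1.53, 110.5, ("chi", 1, 0.0)),
        _t("CG2", "C", ("CB", "CA", "N"), 1.52, 110.5, ("chi", 1, -120.0)),
        _t("CD1", "C", ("CG1", "CB", "CA"), 1.52, 113.8, ("chi", 2, 0.0)),
    ),
    "MET": _chain(
        _t("CG", "C", ("CB", "CA", "N"), 1.52, 114.0, ("chi", 1, 0.0)),
        _t("SD", "S", ("CG", "CB", "CA"), 1.80, 112.7, ("chi", 2, 0.0)),
        _t("CE", "C", ("SD", "CG", "CB"), 1.79, 100.9, ("chi", 3, 0.0)),
    ),
    "PHE": _chain(
        _t("CG", "C", ("CB", "CA", "N"), 1.50, 113.8, ("chi", 1, 0.0)),
        _t("CD1", "C", ("CG", "CB", "CA"), 1.39, 120.0, ("chi", 2, 0.0)),
        _t("CD2", "C", ("CG", "CB", "CA"), 1.39, 120.0, ("chi", 2, 180.0)),
        _t("CE1", "C", ("CD1", "CG", "CB"), 1.39, 120.0, ("fixed", 180.0)),
        _t("CE2", "C", ("CD2", "CG", "CB"), 1.39, 120.0, ("fixed", 180.0)),
        _t("CZ", "C", ("CE1", "CD1", "CG"), 1.39, 120.0, ("fixed", 0.0)),
    ),
    "TYR": _chain(
        _t("CG", "C", ("CB", "CA", "N"), 1.50, 113.8, ("chi", 1, 0.0)),
        _t("CD1", "C", ("CG", "CB", "CA"), 1.39, 120.0, ("chi", 2, 0.0)),
        _t("CD2", "C", ("CG", "CB", "CA"), 1.39, 120.0, ("chi", 2, 180.0)),
        _t("CE1", "C", ("CD1", "CG", "CB"), 1.39, 120.0, ("fixed", 180.0)),
        _t("CE2", "C", ("CD2", "CG", "CB"), 1.39, 120.0, ("fixed", 180.0)),
        _t("CZ", "C", ("CE1", "CD1", "CG"), 1.39, 120.0, ("fixed", 0.0)),
        _t("OH", "O", ("CZ", "CE1", "CD1"), 1.38, 120.0, ("fixed", 180.0)),
    ),
    "TRP": _chain(
        _t("CG", "C", ("CB", "CA", "N"), 1.50, 113.8, ("chi", 1, 0.0)),
        _t("CD1", "C", ("CG", "CB", "CA"), 1.37, 127.0, ("chi", 2, 0.0)),
        _t("CD2", "C", ("CG", "CB", "CA"), 1.43, 126.6, ("chi", 2, 180.0)),
        _t("NE1", "N", ("CD1", "CG", "CB"), 1.38, 110.1, ("fixed", 180.0)),
        _t("CE2", "C", ("CD2", "CG", "CB"), 1.41, 107.0, ("fixed", 180.0)),
        _t("CE3", "C", ("CD2", "CG", "CB"), 1.40, 133.9, ("fixed", 0.0)),
        _t("CZ2", "C", ("CE2", "CD2", "CG"), 1.40, 122.4, ("fixed", 180.0)),
        _t("CZ3", "C", ("CE3", "CD2", "CG"), 1.39, 118.8, ("fixed", 180.0)),
        _t("CH2", "C", ("CZ2", "CE2", "CD2"), 1.37, 117.5, ("fixed", 0.0)),
    ),
    "ASP": _chain(
        _t("CG", "C", ("CB", "CA", "N"), 1.52, 113.0, ("chi", 1, 0.0)),
        _t("OD1", "O", ("CG", "CB", "CA"), 1.25, 118.5, ("chi", 2, 0.0)),
        _t("OD2", "O", ("CG", "CB", "CA"), 1.25, 118.5, ("chi", 2, 180.0)),
    ),
    "ASN": _chain(
        _t("CG", "C", ("CB", "CA", "N"), 1.52, 112.7, ("chi", 1, 0.0)),
        _t("OD1", "O", ("CG", "CB", "CA"), 1.23, 120.8, ("chi", 2, 0.0)),
        _t("ND2", "N", ("CG", "CB", "CA"), 1.33, 116.4, ("chi", 2, 180.0)),
    ),
    "GLU": _chain(
        _t("CG", "C", ("CB", "CA", "N"), 1.52, 114.0, ("chi", 1, 0.0)),
        _t("CD", "C", ("CG", "CB", "CA"), 1.52, 112.6, ("chi", 2, 0.0)),
        _t("OE1", "O", ("CD", "CG", "CB"), 1.25, 118.5, ("chi", 3, 0.0)),
        _t("OE2", "O", ("CD", "CG", "CB"), 1.25, 118.5, ("chi", 3, 180.0)),
    ),
    "GLN": _chain(
        _t("CG", "C", ("CB", "CA", "N"), 1.52, 114.0, ("chi", 1, 0.0)),
        _t("CD", "C", ("CG", "CB", "CA"), 1.52, 112.6, ("chi", 2, 0.0)),
        _t("OE1", "O", ("CD", "CG", "CB"), 1.23, 120.8, ("chi", 3, 0.0)),
        _t("NE2", "N", ("CD", "CG", "CB"), 1.33, 116.4, ("chi", 3, 180.0)),
    ),
    "LYS": _chain(
        _t("CG", "C", ("CB", "CA", "N"), 1.52, 114.0, ("chi", 1, 0.0)),
        _t("CD", "C", ("CG", "CB", "CA"), 1.52, 111.3, ("chi", 2, 0.0)),
        _t("CE", "C", ("CD", "CG", "CB"), 1.52, 111.3, ("chi", 3, 0.0)),
        _t("NZ", "N", ("CE", "CD", "CG"), 1.49, 111.9, ("chi", 4, 0.0)),
    ),
    "ARG": _chain(
        _t("CG", "C", ("CB", "CA", "N"), 1.52, 114.0, ("chi", 1, 0.0)),
        _t("CD", "C", ("CG", "CB", "CA"), 1.52, 111.3, ("chi", 2, 0.0)),
        _t("NE", "N", ("CD", "CG", "CB"), 1.46, 112.0, ("chi", 3, 0.0)),
        _t("CZ", "C", ("NE", "CD", "CG"), 1.33, 124.2, ("chi", 4, 0.0)),
        _t("NH1", "N", ("CZ", "NE", "CD"), 1.33, 120.0, ("fixed", 0.0)),
        _t("NH2", "N", ("CZ", "NE", "CD"), 1.33, 120.0, ("fixed", 180.0)),
    ),
    "HIS": _chain(
        _t("CG", "C", ("CB", "CA", "N"), 1.50, 113.8, ("chi", 1, 0.0)),
        _t("ND1", "N", ("CG", "CB", "CA"), 1.38, 122.7, ("chi", 2, 0.0)),
        _t("CD2", "C", ("CG", "CB", "CA"), 1.36, 131.0, ("chi", 2, 180.0)),
        _t("CE1", "C", ("ND1", "CG", "CB"), 1.32, 109.2, ("fixed", 180.0)),
        _t("NE2", "N", ("CD2", "CG", "CB"), 1.37, 107.2, ("fixed", 180.0)),
    ),
    # fixed ring pucker; no rotatable chis (strained placements get discarded
    # by the clash filter rather than repaired)
    "PRO": _chain(
        _t("CG", "C", ("CB", "CA", "N"), 1.50, 104.5, ("fixed", 30.0)),
        _t("CD", "C", ("CG", "CB", "CA"), 1.51, 106.1, ("fixed", -35.0)),
    ),
}


def n_chis(res_name: str) -> int:
    return max(
        (a.dihedral[1] for a in SIDE_CHAIN_TEMPLATES[res_name] if a.dihedral[0] == "chi"),
        default=0,
    )


def place_atom(c: np.ndarray, b: np.ndarray, a: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """NeRF: position of atom D bonded to C with angle(D,C,B) and
    dihedral(D,C,B,A) given."""
    theta = math.radians(angle_deg)
    phi = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-10:  # colinear reference frame: pick any perpendicular
        helper = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(helper, bc)) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(helper, bc)
        norm = np.linalg.norm(n)
    n /= norm
    m = np.cross(n, bc)
    # the negative n-component makes the measured dihedral D-C-B-A equal to
    # phi under the standard atan2 sign convention
    d_local = np.array([
        -bond * math.cos(theta),
        bond * math.sin(theta) * math.cos(phi),
        -bond * math.sin(theta) * math.sin(phi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_chain_coords(res_name: str, anchor: dict[str, np.ndarray],
                       chis: tuple[float, ...]) -> dict[str, np.ndarray]:
    """Place all template atoms for ``res_name`` given backbone anchor
    positions (must contain N, CA, CB) and chi values in degrees."""
    pos = dict(anchor)
    out: dict[str, np.ndarray] = {}
    for atom in SIDE_CHAIN_TEMPLATES[res_name]:
        kind = atom.dihedral[0]
        if kind == "chi":
            _, k, offset = atom.dihedral
            dih = chis[k - 1] + offset
        else:
            dih = atom.dihedral[1]
        c, b, a = (pos[r] for r in atom.refs)
        p = place_atom(c, b, a, atom.bond, atom.angle, dih)
        pos[atom.name] = p
        out[atom.name] = p
    return out


def clash_score(new_coords: np.ndarray, new_elements: list[str],
                env_tree: cKDTree, env_elements: list[str]) -> tuple[float, float]:
    """Hard-sphere overlap score of new atoms against a fixed environment.

    Returns ``(score, min_contact)`` where score sums squared overlaps of
    scaled vdW spheres and min_contact is the smallest pair distance found.
    """
    if len(new_coords) == 0 or env_tree.n == 0:
        return 0.0, math.inf
    score = 0.0
    min_contact = math.inf
    cutoff = 2 * CLASH_SCALE * max(max(VDW_RADII.values()), DEFAULT_VDW)
    for p, el in zip(new_coords, new_elements):
        r_new = VDW_RADII.get(el, DEFAULT_VDW)
        idx = env_tree.query_ball_point(p, cutoff)
        for j in idx:
            d = float(np.linalg.norm(p - env_tree.data[j]))
            min_contact = min(min_contact, d)
            limit = CLASH_SCALE * (r_new + VDW_RADII.get(env_elements[j], DEFAULT_VDW))
            if d < limit:
                score += (limit - d) ** 2
    return score, min_contact


def search_chis(res_name: str, anchor: dict[str, np.ndarray],
                env_tree: cKDTree, env_elements: list[str],
                grid_step: float = CHI_GRID_STEP) -> tuple[tuple[float, ...], float, float]:
    """Exhaustive chi-grid search minimizing the clash score, then a finer
    deterministic refinement around the winner.

    Ties break toward the lexicographically first grid point; a zero score
    short-circuits (cannot be beaten).  Returns (chis, score, min_contact).
    """
    template = SIDE_CHAIN_TEMPLATES[res_name]
    elements = [a.element for a in template]
    m = n_chis(res_name)

    def evaluate(chis: tuple[float, ...]) -> tuple[float, float]:
        coords = build_chain_coords(res_name, anchor, chis)
        arr = np.array([coords[a.name] for a in template]) if template else np.empty((0, 3))
        return clash_score(arr, elements, env_tree, env_elements)

    if m == 0:
        score, mc = evaluate(())
        return (), score, mc

    grid = [tuple()]
    values = [float(g) for g in np.arange(0.0, 360.0, grid_step)]
    best: tuple[float, ...] | None = None
    best_score = math.inf
    best_mc = math.inf

    def recurse(prefix: tuple[float, ...]):
        nonlocal best, best_score, best_mc
        if best_score == 0.0:
            return
        if len(prefix) == m:
            score, mc = evaluate(prefix)
            if score < best_score:
                best, best_score, best_mc = prefix, score, mc
            return
        for v in values:
            recurse(prefix + (v,))

    recurse(())
    assert best is not None

    # coordinate-wise refinement, two sweeps, only if still clashing
    if best_score > 0.0:
        for _ in range(2):
            for k in range(m):
                for dv in np.arange(-REFINE_SPAN, REFINE_SPAN + 1e-9, REFINE_STEP):
                    cand = tuple(best[i] + (dv if i == k else 0.0) for i in range(m))
                    score, mc = evaluate(cand)
                    if score < best_score:
                        best, best_score, best_mc = cand, score, mc
    return best, best_score, best_mc
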