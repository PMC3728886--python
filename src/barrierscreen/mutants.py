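"""Active-site detection, exhaustive mutant enumeration and side-chain
construction.

The screening universe is defined geometrically: every protein residue with
at least one atom within a cutoff (default 4 Å) of the substrate is an
active-site position, and each non-catalytic position is mutated to all 19
other canonical amino acids.  Double mutants combine, per position, the
single mutant with the lowest barrier.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from . import sidechains
from .errors import SelectionError, StructureError
from .structure import (
    CANONICAL_AA,
    ONE_TO_THREE,
    THREE_TO_ONE,
    Atom,
    Residue,
    Structure,
    residues_within,
)

logger = logging.getLogger(__name__)

#: backbone atom names that are never rebuilt
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT", "H", "HA"})

#: build statuses
STATUS_OK = "OK"
STATUS_DISCARDED_MODELING = "DISCARDED_MODELING"


@dataclass(frozen=True)
class MutationSpec:
    """A single point mutation, e.g. Q127W."""

    chain: str
    seq_number: int
    wt_aa: str
    target_aa: str

    def __post_init__(self):
        if self.wt_aa == self.target_aa:
            raise ValueError(f"mutation {self.label}: target equals wild type")
        if self.target_aa not in ONE_TO_THREE:
            raise ValueError(f"mutation target {self.target_aa!r} is not a canonical amino acid")
        if self.wt_aa not in ONE_TO_THREE:
            raise ValueError(f"wild-type code {self.wt_aa!r} is not a canonical amino acid")

    @property
    def label(self) -> str:
        return f"{self.wt_aa}{self.seq_number}{self.target_aa}"

    @property
    def position(self) -> tuple[str, int]:
        return (self.chain, self.seq_number)


@dataclass(frozen=True)
class DoubleSpec:
    """An unordered pair of single mutations at distinct positions, stored in
    canonical (chain, seq_number) order."""

    first: MutationSpec
    second: MutationSpec

    def __post_init__(self):
        if self.first.position == self.second.position:
            raise ValueError("double mutant requires two distinct positions")
        if self.first.position > self.second.position:
            a, b = self.first, self.second
            object.__setattr__(self, "first", b)
            object.__setattr__(self, "second", a)

    @property
    def label(self) -> str:
        return f"{self.first.label}-{self.second.label}"

    @property
    def specs(self) -> tuple[MutationSpec, MutationSpec]:
        return (self.first, self.second)


@dataclass
class BuildResult:
    """Outcome of a side-chain construction."""

    structure: Structure
    clash_score: float
    min_contact: float
    chis: tuple[float, ...]
    status: str = STATUS_OK


def detect_active_site(s: Structure, r: float = 4.0) -> list[Residue]:
    """Protein residues with at least one atom within ``r`` Å of the
    substrate, sorted by sequence number.

    Catalytic residues are included here; exclusion happens at enumeration.
    """
    center = s.substrate_atoms()
    if not center:
        raise SelectionError("detect_active_site: structure has no substrate atoms")
    hits = residues_within(s, center, r)
    return sorted(hits, key=lambda res: (res.chain, res.seq_number))


def enumerate_single_mutants(
    positions: list[Residue],
    exclusions: set[tuple[str, int]] | set[int] = frozenset(),
) -> list[MutationSpec]:
    """All 19 substitutions at every non-excluded position.

    ``exclusions`` may contain (chain, seq_number) tuples or bare sequence
    numbers.  Output is deterministic: by position, then alphabetical target.
    """
    excl_pairs = {e for e in exclusions if isinstance(e, tuple)}
    excl_nums = {e for e in exclusions if not isinstance(e, tuple)}
    covered = {res.position if hasattr(res, "position") else (res.chain, res.seq_number)
               for res in positions}
    for e in excl_pairs:
        if e not in covered:
            warnings.warn(f"exclusion {e} is not among the given positions")
    for e in excl_nums:
        if not any(seq == e for _, seq in covered):
            warnings.warn(f"exclusion {e} is not among the given positions")

    specs: list[MutationSpec] = []
    for res in sorted(positions, key=lambda r: (r.chain, r.seq_number)):
        pos = (res.chain, res.seq_number)
        if pos in excl_pairs or res.seq_number in excl_nums:
            continue
        wt = THREE_TO_ONE.get(res.res_name)
        if wt is None:
            raise StructureError(f"cannot mutate non-canonical residue {res.res_name}")
        for target in sorted(ONE_TO_THREE):
            if target != wt:
                specs.append(MutationSpec(res.chain, res.seq_number, wt, target))
    return specs


def _anchor_positions(res: Residue) -> dict[str, np.ndarray]:
    """Backbone anchor for side-chain construction; builds CB from N/CA/C
    when the residue lacks one (glycine)."""
    try:
        anchor = {name: res.atom(name).coords.copy() for name in ("N", "CA", "C")}
    except SelectionError as exc:
        raise StructureError(f"unresolvable backbone in {res.res_name} {res.seq_number}") from exc
    if res.has_atom("CB"):
        anchor["CB"] = res.atom("CB").coords.copy()
    else:
        anchor["CB"] = sidechains.place_atom(
            anchor["CA"], anchor["N"], anchor["C"], 1.53, 110.5, 122.5
        )
    return anchor


def build_side_chain(s: Structure, m: MutationSpec, seed: int = 0) -> BuildResult:
    """Replace the side chain at the mutation site.

    Backbone atoms (and an existing CB) keep their coordinates bit-exactly;
    all other atoms of the structure are untouched.  New atoms are placed
    from the ideal template at the clash-minimal chi combination found on a
    deterministic grid.  If after refinement any non-bonded contact between a
    new atom and the environment is shorter than ``sidechains.MIN_CONTACT``
    the result is flagged ``DISCARDED_MODELING`` rather than silently kept.

    ``seed`` is reserved for future stochastic refinement; the default path
    is fully deterministic and ignores it.
    """
    out = s.copy()
    target_res = None
    for res in out.residues:
        if (res.chain, res.seq_number) == m.position:
            target_res = res
            break
    if target_res is None:
        raise SelectionError(f"no residue at {m.position}")
    wt_name = THREE_TO_ONE.get(target_res.res_name)
    if wt_name != m.wt_aa:
        raise StructureError(
            f"{m.label}: structure has {target_res.res_name} at position {m.seq_number}"
        )

    anchor = _anchor_positions(target_res)
    target3 = ONE_TO_THREE[m.target_aa]

    # drop old side-chain atoms (and CB when the target is glycine)
    keep = set(BACKBONE_ATOMS)
    if target3 != "GLY":
        keep.add("CB")
    removed_serials = {a.serial for a in target_res.atoms if a.name not in keep}
    target_res.atoms = [a for a in target_res.atoms if a.name in keep]
    out.links = {l for l in out.links if not (l & removed_serials)}

    # CB may need to be (re)introduced when mutating away from glycine
    if target3 != "GLY" and not target_res.has_atom("CB"):
        target_res.atoms.append(
            Atom(serial=0, name="CB", element="C", coords=anchor["CB"])
        )

    template = sidechains.SIDE_CHAIN_TEMPLATES[target3]
    env_coords, env_elements = [], []
    for res in out.residues:
        for a in res.atoms:
            if res is target_res:
                continue
            env_coords.append(a.coords)
            env_elements.append(a.element)
    env_tree = cKDTree(np.array(env_coords)) if env_coords else cKDTree(np.empty((0, 3)))

    chis, score, min_contact = sidechains.search_chis(target3, anchor, env_tree, env_elements)
    coords = sidechains.build_chain_coords(target3, anchor, chis)

    next_serial = out.max_serial() + 1
    for atom_t in template:
        target_res.atoms.append(
            Atom(serial=next_serial, name=atom_t.name, element=atom_t.element,
                 coords=coords[atom_t.name])
        )
        next_serial += 1
    # give a rebuilt CB a real serial
    for a in target_res.atoms:
        if a.serial == 0:
            a.serial = next_serial
            next_serial += 1
    target_res.res_name = target3

    status = STATUS_OK
    if min_contact < sidechains.MIN_CONTACT:
        status = STATUS_DISCARDED_MODELING
        logger.warning("%s: min contact %.2f Å below %.2f Å — flagged %s",
                       m.label, min_contact, sidechains.MIN_CONTACT, status)
    return BuildResult(structure=out, clash_score=score, min_contact=min_contact,
                       chis=chis, status=status)


def best_per_position(records) -> list[MutationSpec]:
    """One spec per position attaining the minimum barrier; ties break
    alphabetically by target amino acid.

    ``records`` are objects with ``spec`` (MutationSpec) and ``barrier``
    (finite float) attributes.
    """
    by_pos: dict[tuple[str, int], tuple[float, str, MutationSpec]] = {}
    for rec in records:
        if not np.isfinite(rec.barrier):
            raise ValueError(f"record {rec.spec.label} has non-finite barrier")
        key = rec.spec.position
        cand = (rec.barrier, rec.spec.target_aa, rec.spec)
        if key not in by_pos or cand[:2] < by_pos[key][:2]:
            by_pos[key] = cand
    return [by_pos[k][2] for k in sorted(by_pos)]


def enumerate_double_mutants(best: list[MutationSpec]) -> list[DoubleSpec]:
    """All C(P, 2) pairs of distinct positions from the per-position winners."""
    positions = [s.position for s in best]
    if len(positions) != len(set(positions)):
        raise ValueError("enumerate_double_mutants: duplicate position in input")
    ordered = sorted(best, key=lambda s: s.position)
    out = []
    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            out.append(DoubleSpec(ordered[i], ordered[j]))
    return out


def specs_to_csv(specs, statuses: dict[str, str] | None = None) -> str:
    """Serialize mutation specs as CSV (label, chain, position, wt, target,
    status)."""
    import io

    import pandas as pd

    rows = []
    for spec in specs:
        singles = spec.specs if isinstance(spec, DoubleSpec) else (spec,)
        for s in singles:
            rows.append({
                "label": spec.label, "chain": s.chain, "position": s.seq_number,
                "wt": s.wt_aa, "target": s.target_aa,
                "status": (statuses or {}).get(spec.label, ""),
            })
    buf = io.StringIO()
    pd.DataFrame(rows).to_csv(buf, index=False)
    return buf.getvalue()
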