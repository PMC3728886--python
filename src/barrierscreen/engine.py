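"""Uniform engine contract: MOPAC-dialect input writer / output parser,
charge validation and job dispatch.

The semiempirical engine itself (PM6 with the linear-scaling MOZYME scheme)
is external; this module only speaks its file dialect.  Inputs are a keyword
line (method, MOZYME, CHARGE, GNORM, CUTOFF, EPS, CHARGES) followed by a
Cartesian block with per-axis 0/1 optimization flags — a frozen atom gets
``0 0 0``.  Outputs are parsed tolerantly for the final heat of formation,
the final geometry, the engine-reported total charge and known failure
signatures (most importantly the inability to assign a Lewis bonding
pattern, which is used as a discard filter during screening).
"""

from __future__ import annotations

import re
import shutil
import subprocess
import time
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ParseError
from .pathway import ConstraintSet, EMPTY_CONSTRAINTS
from .structure import Structure

# engine statuses
CONVERGED = "CONVERGED"
LEWIS_FAILURE = "LEWIS_FAILURE"
CHARGE_MISMATCH = "CHARGE_MISMATCH"
NOT_CONVERGED = "NOT_CONVERGED"
TIMEOUT = "TIMEOUT"


@dataclass
class EngineConfig:
    """Engine settings.

    gnorm is the gradient-norm convergence threshold in kcal/(mol·Å); cutoff
    the NDDO integral cutoff in Å; eps the continuum-solvent dielectric
    (78 for water).  ``reorthogonalize`` requests a second single-point pass
    with restored orbital orthogonality, recorded alongside the raw energy.
    """

    method_label: str = "PM6"
    gnorm: float = 1.0
    cutoff: float = 15
    eps: float = 78
    charge: int = 0
    reorthogonalize: bool = False
    walltime_limit: float | None = None  # seconds; None = unlimited
    extra_keywords: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.gnorm > 0:
            raise ConfigurationError("gnorm must be positive")
        if not self.cutoff > 0:
            raise ConfigurationError("cutoff must be positive")
        if not self.eps >= 1:
            raise ConfigurationError("eps must be >= 1")


@dataclass
class EngineResult:
    status: str
    final_energy: float | None = None
    final_structure: Structure | None = None
    reported_charge: int | None = None
    wall_time: float = 0.0
    reortho_energy: float | None = None

    def __post_init__(self):
        if self.status == CONVERGED:
            if self.final_energy is None or not np.isfinite(self.final_energy):
                raise ValueError("CONVERGED result requires a finite energy")


def _fmt(x) -> str:
    """Render a keyword value the way the input deck prints it: integers
    without a decimal point, floats as given."""
    if isinstance(x, int) or (isinstance(x, float) and x.is_integer() and abs(x) >= 10):
        return str(int(x))
    return str(x)


def write_engine_input(
    s: Structure,
    k: ConstraintSet | None = None,
    cfg: EngineConfig | None = None,
    frozen_serials: frozenset[int] = frozenset(),
) -> str:
    """Deterministic MOPAC-dialect input text.

    ``frozen_serials`` adds per-job frozen atoms (the reaction-coordinate
    pair during a frame optimization) on top of the constraint set.
    """
    cfg = cfg or EngineConfig()
    k = k or EMPTY_CONSTRAINTS
    fixed = set(k.fixed_serials) | set(frozen_serials)
    keywords = [
        cfg.method_label, "MOZYME",
        f"CHARGE={cfg.charge}",
        f"GNORM={_fmt(cfg.gnorm)}",
        f"CUTOFF={_fmt(cfg.cutoff)}",
        f"EPS={_fmt(cfg.eps)}",
        "CHARGES",
    ]
    keywords.extend(cfg.extra_keywords)
    lines = [" ".join(keywords), f"{s.state_tag} structure, {s.n_atoms} atoms", ""]
    for atom in s.atoms():
        flag = 0 if atom.serial in fixed else 1
        x, y, z = atom.coords
        lines.append(
            f"{atom.element:<2s} {x:15.8f} {flag:d} {y:15.8f} {flag:d} {z:15.8f} {flag:d}"
        )
    return "\n".join(lines) + "\n"


def parse_engine_input(text: str):
    """Recover keywords, elements, coordinates and optimization flags from an
    input deck written by :func:`write_engine_input` (round-trip check)."""
    lines = text.splitlines()
    if len(lines) < 4:
        raise ParseError("input deck too short")
    keywords = lines[0].split()
    atoms = []
    for line in lines[3:]:
        parts = line.split()
        if len(parts) != 7:
            continue
        el = parts[0]
        coords = np.array([float(parts[1]), float(parts[3]), float(parts[5])])
        flags = (int(parts[2]), int(parts[4]), int(parts[6]))
        atoms.append((el, coords, flags))
    return keywords, atoms


#: (regex, status) failure signatures; editable because engine message
#: wording varies across versions
DEFAULT_FAILURE_PATTERNS: tuple[tuple[str, str], ...] = (
    (r"UNABLE TO (GENERATE|RESOLVE)\s+(THE\s+)?LEWIS", LEWIS_FAILURE),
    (r"LEWIS STRUCTURE (COULD NOT|CANNOT) BE", LEWIS_FAILURE),
    (r"FAILED TO ACHIEVE A STABLE LEWIS", LEWIS_FAILURE),
    (r"EXCESS NUMBER OF OPTIMIZATION CYCLES", NOT_CONVERGED),
    (r"GEOMETRY IS NOT FULLY OPTIMIZED", NOT_CONVERGED),
)

_HEAT_RE = re.compile(
    r"FINAL HEAT OF FORMATION\s*=\s*(-?\d+(?:\.\d+)?)\s*(KCAL/MOL|KJ/MOL)", re.I
)
_CHARGE_RE = re.compile(r"(?:COMPUTED\s+)?CHARGE ON SYSTEM\s*[:=]?\s*(-?\d+)", re.I)


def parse_engine_output(
    text: str,
    failure_patterns=DEFAULT_FAILURE_PATTERNS,
) -> EngineResult:
    """Extract the final heat of formation (kcal/mol), the final geometry,
    the reported total charge and the convergence status.

    Raises :class:`ParseError` with a diagnostic excerpt for unrecognizable
    or truncated output.
    """
    if not text.strip():
        raise ParseError("empty engine output")

    for pattern, status in failure_patterns:
        if re.search(pattern, text, re.I):
            result = EngineResult(status=status)
            m = _CHARGE_RE.search(text)
            if m:
                result.reported_charge = int(m.group(1))
            return result

    m = _HEAT_RE.search(text)
    if m is None:
        excerpt = text.strip().splitlines()[-3:]
        raise ParseError(
            "no final heat of formation and no known failure signature; "
            f"tail of output: {excerpt!r}"
        )
    if m.group(2).upper() != "KCAL/MOL":
        raise ParseError(f"unexpected energy unit {m.group(2)!r}; expected KCAL/MOL")
    energy = float(m.group(1))

    result = EngineResult(status=CONVERGED, final_energy=energy)
    cm = _CHARGE_RE.search(text)
    if cm:
        result.reported_charge = int(cm.group(1))

    geom = _parse_geometry_block(text)
    if geom is not None:
        result.final_structure = geom
    return result


def _parse_geometry_block(text: str) -> Structure | None:
    """Parse a 'CARTESIAN COORDINATES' block if present:
    ``index element x y z`` lines."""
    from .structure import Atom, Residue

    lines = text.splitlines()
    start = None
    for i, line in enumerate(lines):
        if "CARTESIAN COORDINATES" in line.upper():
            start = i + 1
    if start is None:
        return None
    atoms = []
    for line in lines[start:]:
        parts = line.split()
        if len(parts) == 5:
            try:
                idx = int(parts[0])
                xyz = [float(parts[2]), float(parts[3]), float(parts[4])]
            except ValueError:
                if atoms:
                    break
                continue
            atoms.append(Atom(serial=idx, name=f"{parts[1]}{idx}", element=parts[1],
                              coords=np.array(xyz)))
        elif atoms:
            break
    if not atoms:
        return None
    return Structure(residues=[Residue(chain="A", seq_number=1, res_name="UNK", atoms=atoms)])


def check_charge(expected: int, r: EngineResult) -> bool:
    """Compare the engine-reported total charge with the formal charge under
    standard protonation.  A mismatch (or a missing report) marks the result
    CHARGE_MISMATCH and fails."""
    if r.reported_charge is None:
        r.status = CHARGE_MISMATCH
        return False
    if r.reported_charge != expected:
        r.status = CHARGE_MISMATCH
        return False
    return True


@dataclass
class EngineJob:
    """One optimization task: a structure, its constraints, the engine
    settings and the engine selection.

    ``engine`` is ``"surrogate"`` (requires ``surface`` and the reaction
    coordinate) or ``"external"`` (requires ``binary``).
    """

    structure: Structure
    config: EngineConfig
    constraints: ConstraintSet = EMPTY_CONSTRAINTS
    engine: str = "surrogate"
    surface: object | None = None
    rc: object | None = None
    mutant_label: str | None = None
    frozen_serials: frozenset[int] = frozenset()
    binary: str | None = None
    workdir: str | None = None
    frame_index: int | None = None


def run_engine(job: EngineJob) -> EngineResult:
    """Dispatch write → execute → parse, enforcing the walltime policy."""
    limit = job.config.walltime_limit
    if limit is not None and limit <= 0:
        return EngineResult(status=TIMEOUT)

    if job.engine == "surrogate":
        if job.surface is None or job.rc is None:
            raise ConfigurationError("surrogate engine requires a surface and a reaction coordinate")
        from .surrogate import surrogate_optimize

        return surrogate_optimize(
            job.structure, job.constraints, job.surface, job.config,
            rc=job.rc, label=job.mutant_label,
            frozen_serials=job.frozen_serials, frame_index=job.frame_index,
        )

    if job.engine == "external":
        if not job.binary or shutil.which(job.binary) is None:
            raise ConfigurationError(
                f"external engine binary {job.binary!r} not found; refusing to fall back silently"
            )
        import os
        import tempfile

        workdir = job.workdir or tempfile.mkdtemp(prefix="engine_")
        deck = write_engine_input(job.structure, job.constraints, job.config,
                                  job.frozen_serials)
        in_path = os.path.join(workdir, "job.mop")
        with open(in_path, "w") as fh:
            fh.write(deck)
        t0 = time.monotonic()
        try:
            subprocess.run([job.binary, in_path], check=False, timeout=limit,
                           capture_output=True)
        except subprocess.TimeoutExpired:
            return EngineResult(status=TIMEOUT, wall_time=time.monotonic() - t0)
        out_path = os.path.join(workdir, "job.out")
        with open(out_path) as fh:
            result = parse_engine_output(fh.read())
        result.wall_time = time.monotonic() - t0
        return result

    raise ConfigurationError(f"unknown engine {job.engine!r}")
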