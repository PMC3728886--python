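"""End-to-end screening: per-mutant reaction profiles, validity filtering,
barrier extraction, ranking, additivity and reorthogonalization analyses, and
transition-state-theory rate conversion.

The barrier of a reaction profile is defined as the highest energy minus the
lowest energy that occurs *before* the highest point.  A profile whose last
frame is the highest is not evaluated (the transition state was not
bracketed), and neither is one whose first frame is the highest (no reactant
side).  Mutants whose preparation or frames fail engine validity checks are
not repaired — they are discarded with an explicit reason and retained in the
filter report.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import engine as eng
from .errors import ConfigurationError
from .mutants import (
    STATUS_DISCARDED_MODELING,
    STATUS_OK,
    DoubleSpec,
    MutationSpec,
    build_side_chain,
)
from .pathway import (
    ConstraintSet,
    EMPTY_CONSTRAINTS,
    ReactionCoordinate,
    build_constraints,
    close_contact_check,
    extract_and_modify_substrate,
    make_frames,
)
from .structure import ProtonationRules, Structure, formal_charge

logger = logging.getLogger(__name__)

# rejection reasons
LAST_FRAME_MAX = "LAST_FRAME_MAX"
NO_PRE_MAX = "NO_PRE_MAX"
INCOMPLETE = "INCOMPLETE"
NONPOSITIVE = "NONPOSITIVE"

# filter statuses beyond the modeling stage
STATUS_LEWIS = "DISCARDED_LEWIS_FAILURE"
STATUS_CHARGE = "DISCARDED_CHARGE_MISMATCH"
STATUS_CONTACT = "DISCARDED_CLOSE_CONTACT"
STATUS_TIMEOUT = "DISCARDED_TIMEOUT"
STATUS_PROFILE_INVALID = "PROFILE_INVALID"

# CODATA 2018
KB = 1.380649e-23          # J/K
H_PLANCK = 6.62607015e-34  # J*s
R_KCAL = 1.98720425864e-3  # kcal/(mol*K)


@dataclass
class ReactionProfile:
    """Ordered frame energies for one mutant (or wild type)."""

    label: str
    pathway_id: int
    x1_targets: list[float]
    energies: list[float | None]
    statuses: list[str]
    layer_radius: float = math.inf
    reortho_energies: list[float | None] | None = None

    def __post_init__(self):
        if len(self.energies) != len(self.x1_targets) or len(self.statuses) != len(self.energies):
            raise ValueError("profile arrays must have equal length")
        for e, st in zip(self.energies, self.statuses):
            if st != eng.CONVERGED and e is not None:
                raise ValueError("energy present for a non-converged frame")


@dataclass
class BarrierResult:
    barrier: float | None
    argmax: int | None
    argmin: int | None
    valid: bool
    rejection_reason: str | None = None


@dataclass
class MutantRecord:
    """A screened mutant: its spec(s), barrier and bookkeeping."""

    spec: MutationSpec | DoubleSpec | None
    label: str
    barrier_result: BarrierResult | None = None
    delta_vs_wt: float | None = None
    status: str = STATUS_OK
    wall_time: float = 0.0
    profile: ReactionProfile | None = None
    reortho_barrier: float | None = None

    @property
    def barrier(self) -> float:
        if self.barrier_result is None or not self.barrier_result.valid:
            return math.nan
        return self.barrier_result.barrier

    @property
    def valid(self) -> bool:
        return (self.status == STATUS_OK and self.barrier_result is not None
                and self.barrier_result.valid)


def extract_barrier(p: ReactionProfile) -> BarrierResult:
    """Apply the barrier rule to a reaction profile.

    argmax is the first index of the global maximum; the barrier is the
    maximum energy minus the minimum energy among frames strictly before it.
    Rejections (in precedence order when several could apply): INCOMPLETE if
    any frame before the maximum did not converge, LAST_FRAME_MAX if the
    final frame is the maximum, NO_PRE_MAX if the first frame is, and
    NONPOSITIVE if the resulting barrier is not > 0.
    """
    conv = [(i, e) for i, (e, st) in enumerate(zip(p.energies, p.statuses))
            if st == eng.CONVERGED]
    if len(conv) < 2:
        return BarrierResult(None, None, None, False, INCOMPLETE)
    emax = max(e for _, e in conv)
    argmax = next(i for i, e in conv if e == emax)
    if any(st != eng.CONVERGED for st in p.statuses[:argmax]):
        return BarrierResult(None, argmax, None, False, INCOMPLETE)
    if argmax == len(p.energies) - 1:
        return BarrierResult(None, argmax, None, False, LAST_FRAME_MAX)
    if argmax == 0:
        return BarrierResult(None, argmax, None, False, NO_PRE_MAX)
    prefix = p.energies[:argmax]
    emin = min(prefix)
    argmin = prefix.index(emin)
    barrier = emax - emin
    if not barrier > 0:
        return BarrierResult(barrier, argmax, argmin, False, NONPOSITIVE)
    return BarrierResult(barrier, argmax, argmin, True, None)


def delta_barrier(mut: MutantRecord, wt: MutantRecord) -> float:
    """Change in barrier height relative to the reference record."""
    if not (mut.valid and wt.valid):
        raise ValueError("delta_barrier: both records must carry valid barriers")
    return mut.barrier - wt.barrier


# -- transition state theory --------------------------------------------------

def eyring_dg(k_cat: float, T: float) -> float:
    """Activation free energy (kcal/mol) from a rate constant via the Eyring
    equation: dG = R*T*ln(kB*T / (h*k))."""
    if k_cat <= 0 or T <= 0:
        raise ValueError("eyring_dg requires positive rate and temperature")
    return R_KCAL * T * math.log(KB * T / (H_PLANCK * k_cat))


def eyring_k(dg: float, T: float) -> float:
    """Rate constant (1/s) from an activation free energy; exact inverse of
    :func:`eyring_dg`."""
    if T <= 0:
        raise ValueError("eyring_k requires positive temperature")
    return KB * T / H_PLANCK * math.exp(-dg / (R_KCAL * T))


# -- orchestration -------------------------------------------------------------

@dataclass
class ScreenSettings:
    n_intermediate: int = 10
    layer_radius: float = 10.0
    dmin: float = 0.7
    pathway_id: int = 5
    engine_config: eng.EngineConfig = field(default_factory=eng.EngineConfig)
    check_charges: bool = True


@dataclass
class ScreeningContext:
    """Everything the per-mutant pipeline needs besides the specs."""

    wt_ge_opt: Structure
    wt_es_prime_opt: Structure
    rc: ReactionCoordinate
    surface: object = None            # SurrogateSurface for engine="surrogate"
    engine: str = "surrogate"
    binary: str | None = None
    rules: ProtonationRules | None = None
    substrate_charge: int | None = None


def _expected_charge(structure: Structure, ctx: ScreeningContext) -> int | None:
    if ctx.rules is None:
        return None
    return formal_charge(structure, ctx.rules)


def _run_job(structure, constraints, settings, ctx, label, frozen=frozenset(),
             frame_index=None) -> eng.EngineResult:
    config = settings.engine_config
    if ctx.rules is not None:
        # the deck always carries the formal charge under standard protonation;
        # the engine's own charge perception is validated against it afterwards
        config = replace(config, charge=formal_charge(structure, ctx.rules))
    job = eng.EngineJob(
        structure=structure, config=config, constraints=constraints,
        engine=ctx.engine, surface=ctx.surface, rc=ctx.rc, mutant_label=label,
        frozen_serials=frozenset(frozen), binary=ctx.binary, frame_index=frame_index,
    )
    return eng.run_engine(job)


def compute_profile(
    es: Structure,
    ge: Structure,
    ctx: ScreeningContext,
    settings: ScreenSettings,
    label: str,
    constraints: ConstraintSet | None = None,
) -> tuple[ReactionProfile, str]:
    """Frames, per-frame engine jobs and validity checks for one endpoint
    pair.  Returns the profile and an overall status."""
    frames = make_frames(es, ge, ctx.rc, settings.n_intermediate, constraints)
    frozen = frozenset(ctx.rc.serials(es))
    energies: list[float | None] = []
    statuses: list[str] = []
    reortho: list[float | None] = []
    status = STATUS_OK
    for frame in frames:
        ok, pairs = close_contact_check(frame, settings.dmin)
        if not ok:
            logger.warning("%s frame %d: %d close contacts", label, frame.index, len(pairs))
            return (
                ReactionProfile(label, settings.pathway_id,
                                [f.x1_target for f in frames],
                                [None] * len(frames), ["CLOSE_CONTACT"] * len(frames),
                                settings.layer_radius),
                STATUS_CONTACT,
            )
        result = _run_job(frame.structure, frame.constraint, settings, ctx, label,
                          frozen=frozen, frame_index=frame.index)
        if result.status == eng.TIMEOUT:
            status = STATUS_TIMEOUT
        elif result.status == eng.LEWIS_FAILURE:
            status = STATUS_LEWIS
        statuses.append(result.status)
        energies.append(result.final_energy if result.status == eng.CONVERGED else None)
        reortho.append(result.reortho_energy)
    profile = ReactionProfile(
        label=label, pathway_id=settings.pathway_id,
        x1_targets=[f.x1_target for f in frames],
        energies=energies, statuses=statuses,
        layer_radius=settings.layer_radius,
        reortho_energies=reortho if any(r is not None for r in reortho) else None,
    )
    return profile, status


def run_wild_type(ctx: ScreeningContext, settings: ScreenSettings) -> MutantRecord:
    """Wild-type reference profile (derivation pathway 2 endpoints: the
    optimized GE and the ES' derived from it)."""
    constraints = _layer_constraints(ctx.wt_ge_opt, ctx, settings)
    profile, status = compute_profile(ctx.wt_es_prime_opt, ctx.wt_ge_opt, ctx,
                                      settings, "WT", constraints)
    record = MutantRecord(spec=None, label="WT", profile=profile, status=status)
    if status == STATUS_OK:
        record.barrier_result = extract_barrier(profile)
        if not record.barrier_result.valid:
            record.status = STATUS_PROFILE_INVALID
        record.reortho_barrier = _reortho_barrier(profile)
    return record


def _layer_constraints(structure, ctx, settings) -> ConstraintSet | None:
    if math.isinf(settings.layer_radius):
        return None
    return build_constraints(structure, structure.substrate_atoms(),
                             settings.layer_radius, ctx.rc)


def _reortho_barrier(profile: ReactionProfile) -> float | None:
    if profile.reortho_energies is None:
        return None
    alt = ReactionProfile(
        label=profile.label, pathway_id=profile.pathway_id,
        x1_targets=profile.x1_targets,
        energies=[e if st == eng.CONVERGED else None
                  for e, st in zip(profile.reortho_energies, profile.statuses)],
        statuses=profile.statuses, layer_radius=profile.layer_radius,
    )
    res = extract_barrier(alt)
    return res.barrier if res.valid else None


def screen(
    specs: list[MutationSpec | DoubleSpec],
    wt_record: MutantRecord,
    ctx: ScreeningContext,
    settings: ScreenSettings | None = None,
) -> tuple[list[MutantRecord], dict]:
    """Per-mutant pipeline (derivation pathway 5 by default): build side
    chain(s) on the optimized GE, optimize, transplant the wild-type ES'
    substrate pose, optimize, interpolate, run the engine per frame, filter,
    and extract the barrier.  Discarded mutants stay in the report with their
    reason.
    """
    settings = settings or ScreenSettings()
    if not wt_record.valid:
        raise ConfigurationError("screen: wild-type record is invalid; aborting")

    records: list[MutantRecord] = []
    report: dict[str, list[str]] = {}

    for spec in specs:
        t0 = time.monotonic()
        label = spec.label
        singles = spec.specs if isinstance(spec, DoubleSpec) else (spec,)

        # 1. side-chain construction on the optimized GE
        structure = ctx.wt_ge_opt
        build_status = STATUS_OK
        for single in singles:
            built = build_side_chain(structure, single)
            structure = built.structure
            if built.status == STATUS_DISCARDED_MODELING:
                build_status = STATUS_DISCARDED_MODELING
                break
        if build_status != STATUS_OK:
            rec = MutantRecord(spec=spec, label=label, status=STATUS_DISCARDED_MODELING,
                               wall_time=time.monotonic() - t0)
            records.append(rec)
            report.setdefault(STATUS_DISCARDED_MODELING, []).append(label)
            continue

        # 2. optimize the mutant GE under the layer constraints
        constraints = _layer_constraints(structure, ctx, settings)
        result = _run_job(structure, constraints or EMPTY_CONSTRAINTS, settings, ctx, label)
        rec = MutantRecord(spec=spec, label=label)
        if result.status == eng.LEWIS_FAILURE:
            rec.status = STATUS_LEWIS
        elif result.status == eng.TIMEOUT:
            rec.status = STATUS_TIMEOUT
        elif settings.check_charges and ctx.rules is not None:
            expected = _expected_charge(structure, ctx)
            if not eng.check_charge(expected, result):
                rec.status = STATUS_CHARGE
        if rec.status != STATUS_OK:
            rec.wall_time = time.monotonic() - t0
            records.append(rec)
            report.setdefault(rec.status, []).append(label)
            continue
        mut_ge_opt = result.final_structure

        # 3. transplant the non-covalent substrate pose and optimize ES''
        mut_es = extract_and_modify_substrate(mut_ge_opt, ctx.wt_es_prime_opt)
        es_result = _run_job(mut_es, constraints or EMPTY_CONSTRAINTS, settings, ctx, label)
        if es_result.status != eng.CONVERGED:
            rec.status = (STATUS_LEWIS if es_result.status == eng.LEWIS_FAILURE
                          else STATUS_TIMEOUT if es_result.status == eng.TIMEOUT
                          else STATUS_PROFILE_INVALID)
            rec.wall_time = time.monotonic() - t0
            records.append(rec)
            report.setdefault(rec.status, []).append(label)
            continue
        mut_es_opt = es_result.final_structure

        # 4. frames, engine per frame, filters, barrier
        profile, status = compute_profile(mut_es_opt, mut_ge_opt, ctx, settings,
                                          label, constraints)
        rec.profile = profile
        rec.status = status
        if status == STATUS_OK:
            rec.barrier_result = extract_barrier(profile)
            if rec.barrier_result.valid:
                rec.delta_vs_wt = rec.barrier - wt_record.barrier
                rec.reortho_barrier = _reortho_barrier(profile)
            else:
                rec.status = STATUS_PROFILE_INVALID
        rec.wall_time = time.monotonic() - t0
        records.append(rec)
        if rec.status != STATUS_OK:
            report.setdefault(rec.status, []).append(label)

    report_summary = {
        "n_requested": len(specs),
        "n_computed": sum(1 for r in records if r.valid),
        "n_discarded": sum(1 for r in records if not r.valid),
        "by_reason": {k: sorted(v) for k, v in report.items()},
    }
    return records, report_summary


def rank(records: list[MutantRecord], top_n: int | None = None) -> pd.DataFrame:
    """Valid records sorted ascending by barrier (stable tie-break by label)."""
    if not records:
        raise ValueError("rank: no records")
    rows = [
        {"label": r.label, "barrier": r.barrier, "delta_vs_wt": r.delta_vs_wt,
         "status": r.status}
        for r in sorted((r for r in records if r.valid),
                        key=lambda r: (r.barrier, r.label))
    ]
    df = pd.DataFrame(rows, columns=["label", "barrier", "delta_vs_wt", "status"])
    return df.head(top_n) if top_n is not None else df


def additivity_analysis(
    singles: list[MutantRecord],
    doubles: list[MutantRecord],
    wt: MutantRecord,
    display_cap: float = 30.0,
) -> tuple[pd.DataFrame, dict]:
    """Expected vs observed double-mutant barriers under additivity.

    expected(A-B) = barrier(A) + barrier(B) − barrier(WT).  Doubles with a
    missing or invalid constituent single are excluded with a warning.  The
    summary reports distribution means (restricted to barriers below
    ``display_cap`` for comparability with capped histograms) and the
    residual statistics over all analysed doubles.
    """
    single_by_label = {r.label: r for r in singles if r.valid}
    rows = []
    excluded = []
    for rec in doubles:
        if not rec.valid:
            excluded.append(rec.label)
            continue
        parts = rec.label.split("-")
        if len(parts) != 2 or any(p not in single_by_label for p in parts):
            logger.warning("double %s: constituent single missing; excluded", rec.label)
            excluded.append(rec.label)
            continue
        b1 = single_by_label[parts[0]].barrier
        b2 = single_by_label[parts[1]].barrier
        expected = b1 + b2 - wt.barrier
        rows.append({
            "label": rec.label, "observed": rec.barrier, "expected": expected,
            "residual": rec.barrier - expected,
        })
    df = pd.DataFrame(rows, columns=["label", "observed", "expected", "residual"])
    singles_capped = [r.barrier for r in singles if r.valid and r.barrier < display_cap]
    doubles_capped = [r.barrier for r in doubles if r.valid and r.barrier < display_cap]
    summary = {
        "mean_single_barrier": float(np.mean(singles_capped)) if singles_capped else math.nan,
        "mean_double_barrier": float(np.mean(doubles_capped)) if doubles_capped else math.nan,
        "mean_residual": float(df["residual"].mean()) if len(df) else math.nan,
        "max_abs_residual": float(df["residual"].abs().max()) if len(df) else math.nan,
        "n_analysed": len(df),
        "n_excluded": len(excluded),
        "display_cap": display_cap,
    }
    return df, summary


@dataclass
class AgreementResult:
    quadrant_counts: tuple[int, int, int, int]
    n_total: int
    agreement_pct: int


def reortho_agreement(
    records: list[MutantRecord],
    wt_raw: float,
    wt_reortho: float,
    cap: float = 34.0,
) -> AgreementResult:
    """Qualitative agreement between raw and reorthogonalized barriers.

    Each mutant is classified by the sign of (barrier − WT barrier) under
    both energy variants: quadrant 1 = higher/higher, 2 = lower/higher,
    3 = lower/lower, 4 = higher/lower (a barrier exactly equal to the
    reference counts as higher).  Only mutants with both barriers below
    ``cap`` enter; agreement is (q1 + q3) / total, rounded to the nearest
    integer percent.
    """
    counts = [0, 0, 0, 0]
    for rec in records:
        if not rec.valid or rec.reortho_barrier is None:
            continue
        if rec.barrier >= cap or rec.reortho_barrier >= cap:
            continue
        raw_higher = rec.barrier >= wt_raw
        reo_higher = rec.reortho_barrier >= wt_reortho
        if raw_higher and reo_higher:
            counts[0] += 1
        elif not raw_higher and reo_higher:
            counts[1] += 1
        elif not raw_higher and not reo_higher:
            counts[2] += 1
        else:
            counts[3] += 1
    total = sum(counts)
    pct = int(round(100.0 * (counts[0] + counts[2]) / total)) if total else 0
    return AgreementResult(tuple(counts), total, pct)


def agreement_from_counts(counts: tuple[int, int, int, int]) -> int:
    """Agreement percentage from quadrant counts (quadrants 1 and 3 agree)."""
    total = sum(counts)
    if total == 0:
        return 0
    return int(round(100.0 * (counts[0] + counts[2]) / total))


def records_to_frame(records: list[MutantRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "label": r.label,
            "barrier": r.barrier,
            "delta_vs_wt": r.delta_vs_wt,
            "status": r.status,
            "rejection": (r.barrier_result.rejection_reason
                          if r.barrier_result is not None else None),
            "wall_time_s": r.wall_time,
        })
    return pd.DataFrame(rows)
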