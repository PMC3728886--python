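# Methods

## Model

The rate-limiting glycosylation step of a retaining glycoside hydrolase is
bracketed by the enzyme–substrate complex (ES) and the covalent
glycosyl-enzyme intermediate (GE). The reaction coordinate x₁ is the distance
between the nucleophile carboxylate oxygen (Oε) and the anomeric carbon C₁.
A reaction profile is obtained by adiabatic mapping: `n + 2` frames (default
`n = 10` intermediates) are placed at x₁ targets forming an arithmetic
progression between the ES and GE values, `t_k = k/(n+1)`. Intermediate
geometries are the linear blend `(1−t)·ES + t·GE`; the x₁ target of each
frame is then enforced exactly (to 10⁻⁶ Å) by rescaling the C₁ position along
the Oε→C₁ axis. At each frame the energy engine relaxes all degrees of
freedom except x₁ (the two reaction-coordinate atoms are frozen per frame)
and any atoms in the constraint set.

**Barrier rule.** The barrier is the highest frame energy minus the lowest
energy occurring *before* the highest. A profile is rejected — never patched —
when (in precedence order) a frame before the maximum failed to converge
(`INCOMPLETE`), the final frame is the maximum (`LAST_FRAME_MAX`, the
transition state was not bracketed), the first frame is the maximum
(`NO_PRE_MAX`), or the resulting barrier is not positive (`NONPOSITIVE`).
The precedence order is a documented choice: an unconverged prefix makes any
statement about the maximum unreliable, so it dominates.

**Endpoint derivation.** Five pathways are supported. Pathway 2 (wild type)
derives ES′ from the optimized GE by breaking the Oε–C₁ ester link,
re-forming the glycosidic C₁–O(phenolic) bond at 1.43 Å and rigid-body
translating the leaving-group fragment. Pathway 5 (mutants, the production
route) mutates the optimized GE, optimizes, transplants the wild-type ES′
substrate pose onto the mutant protein, and optimizes again; this keeps the
protein environment of both endpoints consistent. Pathway 3 models both
endpoints independently and therefore cannot be combined with Cartesian
constraints (frozen outer-layer coordinates would disagree between
endpoints); the planner rejects that combination.

**Constraint set K.** All atoms of protein residues with no atom within a
layer radius (default 10 Å) of the active center are frozen to their
coordinates in the origin endpoint (GE). Substrate residues are always
mobile and reaction-coordinate atoms are never members of K.

**Mutant construction.** Active-site positions are protein residues with at
least one atom within 4 Å of the substrate. Each non-catalytic position is
mutated to the 19 other canonical amino acids. Side chains are rebuilt from
ideal internal-coordinate templates by NeRF placement: an exhaustive 30° grid
over up to four χ angles minimizes a hard-sphere clash score (vdW radii
scaled by 0.8), followed by deterministic ±15°/5° coordinate-wise refinement.
If the best placement still leaves a non-bonded contact under 1.5 Å the
mutant is flagged `DISCARDED_MODELING`. Backbone atoms and an existing CB are
preserved bit-exactly. Double mutants combine the lowest-barrier single per
position, all C(P, 2) pairs.

## Engine contract and parameters

The external engine (semiempirical PM6 with the linear-scaling MOZYME scheme)
is addressed only through its file dialect: a keyword line
(`PM6 MOZYME CHARGE=… GNORM=… CUTOFF=… EPS=… CHARGES`) and a Cartesian block
with per-axis 0/1 optimization flags (frozen atom = `0 0 0`). Defaults:
gradient norm 1.0 kcal/(mol·Å), integral cutoff 15 Å, continuum dielectric
78 (water). Output parsing extracts the final heat of formation (kcal/mol,
unit asserted), the final geometry, and the engine-reported total charge;
known failure signatures (inability to assign a Lewis bonding pattern, cycle
exhaustion) map to explicit statuses. The reported charge is validated
against the formal charge under standard protonation rules (Asp/Glu −1,
Lys/Arg +1, charged termini, declared hetero-group charges); a mismatch
discards the mutant, because it indicates the engine perceived different
chemistry than intended.

Rates and barriers interconvert through the Eyring equation
ΔG‡ = RT·ln(k_B·T/(h·k)) with CODATA 2018 constants; 9.6 s⁻¹ at 313.15 K
corresponds to 17.0 kcal/mol.

## Surrogate surface design

Real semiempirical barriers are not desk-reproducible, so correctness of the
pipeline is demonstrated against an analytic surrogate with *programmable*
ground truth. Along the reduced coordinate `u = (x₁ − x₁ᴱˢ)/(x₁ᴳᴱ − x₁ᴱˢ)`
the energy is

```
E(u) = B(label) · bump(u) + ΔE_rxn · step(u) + walls outside [0, 1]
```

plus harmonic tethers on non-reacting atoms. `bump` is a C¹ hill built from
smoothstep pieces with a **flat top**: rise on u ∈ [0.25, 0.45], plateau at 1
on [0.45, 0.55], fall on [0.55, 0.75]. The flat top is the key design
decision: the default 12-frame ladder places frames at u = 5/11 ≈ 0.4545 and
6/11 ≈ 0.5455, both on the plateau, so the recovered barrier equals the
programmed `B(label)` *exactly* rather than to within a curvature-dependent
sampling error (a round-topped hill such as a Gaussian cannot satisfy a tight
recovery tolerance at 12 frames — the maximum always falls between frames).
Coarser ladders under-sample the hill (4 intermediates recover only ≈ 84 % of
B), so convergence of the recovered barrier with frame count is an observable
property, which the tests exercise.

`B(label)` is the wild-type height plus a per-mutant offset; unprogrammed
double labels fall back to the sum of their single offsets, which makes the
additivity analysis exactly verifiable. Optional i.i.d. Gaussian noise
(seeded per label and frame through a CRC32-keyed generator, hence
process-stable) emulates optimizer scatter; a separate stream perturbs
reorthogonalized energies. Specific labels can be programmed to fail with a
Lewis-structure error or to report a wrong total charge, exercising the
discard filters end to end. Tether centers default to the starting
coordinates, so endpoint optimizations are stationary by construction and the
surrogate descent never reports an energy above its start.

## Synthetic fixtures

The toy system is a miniature active-site analog: a glutamate nucleophile
whose OE1 sits at x₁ᴳᴱ from C₁, a two-fragment substrate (sugar-like fragment
with C₁; phenolate-like leaving group with O₁, formal charge −1), and alanine
shell residues on a golden-angle spiral at controlled radii — inside 4 Å for
programmed active-site members, 7 Å and beyond for the rest. Placement is a
pure function of the spec seed; jittered placements are screened
deterministically (active-site count must match the spec and no non-bonded
pair may start below the 0.7 Å close-contact radius), retrying derived jitter
seeds until a clean geometry appears. Positions can be "walled in" with a
ring of blocker atoms on the CG circle, guaranteeing that any side chain
extending beyond CB clashes — this makes the `DISCARDED_MODELING` path
testable. ES and GE are bit-identical outside the substrate, which is what
makes linear interpolation between them meaningful.

## Limitations

- The surrogate demonstrates pipeline correctness, not chemistry: recovered
  barriers are exact because the surface is designed to make them so. Against
  a real engine the method inherits all errors of semiempirical adiabatic
  mapping (no transition-state refinement, single reaction coordinate, no
  conformational sampling, no zero-point or entropic corrections).
- Side-chain construction is a clash-minimal single rotamer on ideal
  geometry; it does not repack neighbors or sample backbone relaxation.
- The benchmark-scale comparison (wild-type barrier on a real xylanase
  system, ≈ 18.5 kcal/mol unconstrained vs ≈ 13.4 kcal/mol with a 10 Å layer)
  requires the external engine and cluster time and is out of scope for the
  test suite; only the engine file contract is verified here.
- The barrier rule reads frame energies as-is; it cannot detect a maximum
  that falls between frames (mitigated by the frame-count convergence checks)
  or distinguish a true transition state from an artifact of the constrained
  interpolation path.
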