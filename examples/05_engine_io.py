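"""Write and parse engine files in the MOPAC dialect.

The external engine is optional: this example only exercises the file
contract -- a keyword line plus a Cartesian block with per-axis 0/1
optimization flags -- and the tolerant output parser with its failure
signatures (Lewis-structure failure, cycle exhaustion).
"""

import barrierscreen as bs
from barrierscreen import engine as eng

system = bs.make_toy_system(bs.ToySystemSpec(seed=7))

cfg = eng.EngineConfig(charge=bs.formal_charge(system.ge, system.rules),
                       gnorm=0.5, eps=78)
k = bs.build_constraints(system.ge, system.ge.substrate_atoms(), 6.0, system.rc)
deck = eng.write_engine_input(system.ge, k, cfg,
                              frozen_serials=frozenset(system.rc.serials(system.ge)))
print("--- input deck (first 6 lines) ---")
print("\n".join(deck.splitlines()[:6]))

keywords, atoms = eng.parse_engine_input(deck)
n_frozen = sum(1 for _, _, flags in atoms if flags == (0, 0, 0))
print(f"\nround-trip: {len(atoms)} atoms, {n_frozen} frozen")

fake_output = """
  FINAL HEAT OF FORMATION =   -512.34567 KCAL/MOL
  COMPUTED CHARGE ON SYSTEM: -2
"""
result = eng.parse_engine_output(fake_output)
print(f"parsed: status={result.status}, "
      f"E={result.final_energy} kcal/mol, charge={result.reported_charge}")
print("charge check passes:",
      eng.check_charge(bs.formal_charge(system.ge, system.rules), result))

failure = eng.parse_engine_output("UNABLE TO GENERATE THE LEWIS STRUCTURE")
print(f"failure signature recognized: {failure.status}")
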