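"""Derive reaction endpoints and build the interpolation frame ladder.

Starting from the covalent glycosyl-enzyme intermediate (GE), the
enzyme-substrate complex (ES) is re-derived by breaking the nucleophile-C1
ester link and re-forming the glycosidic bond to the leaving group.  The
reaction profile is then mapped on 12 frames whose reaction coordinate x1
forms an arithmetic progression between the two endpoints.
"""

import barrierscreen as bs

system = bs.make_toy_system(bs.ToySystemSpec(seed=7))

# endpoint derivation (pathway 2: ES' from the optimized GE).  Only the
# leaving group moves; the nucleophile-C1 link is broken in the registry and
# the glycosidic bond re-formed at its standard length.
es_prime = bs.derive_es_from_ge(system.ge, system.rc, system.phenolic)
c1 = system.rc.atom_b.resolve(es_prime)
o1 = system.phenolic.resolve(es_prime)
import numpy as np
print(f"derived ES': new C1-O(phenolic) bond = "
      f"{np.linalg.norm(c1.coords - o1.coords):.2f} A, "
      f"nucleophile link broken = "
      f"{not es_prime.are_linked(system.rc.atom_a.resolve(es_prime), c1)}")

# constraint set: freeze residues with no atom within 6 A of the substrate
k = bs.build_constraints(system.ge, system.ge.substrate_atoms(), 6.0, system.rc)
print(f"constraint set: {len(k)} frozen atoms at layer radius {k.layer_radius} A")

# 10 intermediate frames + 2 endpoints
frames = bs.make_frames(system.es, system.ge, system.rc, 10, k)
print("x1 ladder:", " ".join(f"{f.x1_target:.2f}" for f in frames))

for f in frames:
    ok, pairs = bs.close_contact_check(f, 0.7)
    assert ok, f"frame {f.index} has close contacts: {pairs}"
print("all frames pass the 0.7 A close-contact filter")

bs.write_frames(frames, "scratch/frames.pdb", "scratch/frames.json")
print("frames written to scratch/frames.pdb (+ sidecar)")
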