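"""Decompose the normal-mode motion of a synthetic chain.

Builds an idealized 60-residue helix/sheet/coil Cα trace, computes all
elastic-network normal modes, and splits each residue's 9-residue-segment
fluctuation into a rigid-body (external) and a deformation (internal) part.
"""

import numpy as np

import flexmotion as fm

SS = "CCCHHHHHHHHHHCCCCEEEEEECCCCHHHHHHHHCCCCEEEEEECCCCHHHHHHHHCCC"

spec = fm.TopologySpec(ss_string=SS, jitter=0.15, seed=5)
structure = fm.generate_toy_structure(spec)
modes = fm.build_anm_modes(structure, cutoff=13.0)
profile = fm.compute_motion_profile(structure, modes, segment_length=9)

print(f"chain of {len(structure)} residues, {modes.n_modes} non-rigid modes")
for name, ss_char in [("coil", "C"), ("helix", "H"), ("sheet", "E")]:
    sel = np.array(list(SS)) == ss_char
    print(
        f"  mean internal motion in {name:5s}: "
        f"{profile.internal[sel].mean():6.3f}  "
        f"external: {profile.external[sel].mean():6.3f}"
    )

frac = fm.cross_term_fraction(structure, modes)
print(f"median cross term: {np.nanmedian(frac) * 100:.3f}% of (ext² + int²)")
print(
    "Helix cores move largely as rigid bodies (lowest internal motion)\n"
    "while loops and strand edges deform; the interference term between\n"
    "the two parts is negligible, so the decomposition is effectively exact."
)
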