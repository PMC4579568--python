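"""Enumerate the stalkhead separations allowed by the MT lattice.

On a 14-protofilament, 3-start microtubule, binding sites repeat every
8.3 nm along a protofilament and adjacent protofilaments are staggered by
0.9 nm.  The separations between the two track-binding stalkheads of a
dimer are therefore quantized; the values printed below are the discrete
classes the analysis assigns dimers to.
"""

from dyneinflex import LatticeParams, separation_classes, site_axial_offset

lattice = LatticeParams()
print(f"lattice: {lattice.axial_repeat} nm repeat, "
      f"{lattice.pf_stagger} nm stagger, {lattice.n_protofilaments} pf")

print("\nallowed stalkhead separations (nm) up to 3 repeats, off-seam:")
print(" ", ", ".join(f"{s:.1f}" for s in separation_classes(3)))

seam = site_axial_offset(1, 1, crosses_seam=True)
print(f"\none repeat + one stagger across the seam: {seam:.1f} nm")
print("(the seam adds ~4 nm, blurring the histogram of measured separations)")
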