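"""Detect a productive ssODN self-dimer and reconstruct its insertion.

The packaged 70-nt single-base-repair oligo (40 + 1 + 29 design) ends in an
8-nt self-complementary stretch.  Two copies annealed 3'-end-to-3'-end form
a productive dimer (recessed 3' ends, protruding 5' tails) that can engage
the staggered Cas12a cut and template an in-line insertion of one full
oligo copy — net +48 bp after 5' flap trimming, 5-nt microhomology capture
and upstream resection.
"""

from exactsim import dimer_insertion_repair, filter_productive_dimers, scan_self_dimers
from exactsim.synthetic import fixtures

fix = fixtures("F_DIMER")
geoms = scan_self_dimers(fix.oligo, min_overlap=4)
print(f"oligo ({len(fix.oligo.seq)} nt): {fix.oligo.seq}")
print(f"{len(geoms)} self-dimer geometries; strongest five:")
for g in geoms[:5]:
    print(
        f"  overlap {g.overlap_len:>2} nt  dG {g.delta_g:>7.2f} kcal/mol  {g.end_state}"
    )

productive = filter_productive_dimers(geoms)
top = productive[0]
print(f"\ntop productive geometry: overlap {top.overlap_len} nt, dG {top.delta_g} kcal/mol")
print("(3'-overhang geometries cannot associate with the cut ends and are rejected)")

product = dimer_insertion_repair(fix.locus, fix.junction, fix.oligo, top)
print(f"\nreconstructed product: net {product.net_indel:+d} bp ({product.pathway})")
print(f"incorporated oligo copy (after 2-nt flap trim): {product.detail['incorporated']}")
print(f"upstream bases resected: {product.detail['resected_interval']}")
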