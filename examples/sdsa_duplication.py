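"""Predict the duplication side product of two-step SDSA repair.

When the upstream flank's cut-proximal bases occur a second time inside the
repair oligo's homology arm, the extending strand can misprime there and
copy the bases between that alternative anneal site and the cut twice.
This script engineers such a locus (terminal 5-mer GCATT repeated at the
arm's far end, 8 nt upstream of the cut) and shows both outcomes.
"""

from exactsim import Edit, Oligo, sdsa_two_step_repair

locus = "ACCTGAA" + "GCATT" + "CAT" + "GCATT" + "GTACGATTACGGTCA"
junction = 20
edit = Edit(kind="insertion", payload="GG")
oligo = Oligo(
    seq=locus[7:20] + "GG" + locus[20:30],
    left_arm_len=13,
    right_arm_len=10,
    edit=edit,
    orientation="S",
)

print(f"locus {locus}, cut at {junction}, 13-nt upstream arm, +GG edit")
for product in sdsa_two_step_repair(locus, junction, oligo, min_anneal=5):
    if "duplication_span" in product.detail:
        m, j = product.detail["duplication_span"]
        print(
            f"duplication product: net {product.net_indel:+d} bp; "
            f"bases [{m},{j}) = {product.detail['duplicated']} copied twice"
        )
    else:
        print(f"perfect product:     net {product.net_indel:+d} bp")
    print(f"  {product.seq}")
print("\nThe duplication carries the programmed edit plus a tandem copy of the")
print("8 bases between the alternative anneal site and the cut.")
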