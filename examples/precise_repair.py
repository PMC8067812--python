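"""Precise ssODN-templated repair: insert a NotI site at a Cas9 cut.

Builds the packaged 36+8+36 knock-in design (36-nt homology arms flanking
the 8-nt NotI recognition sequence GCGGCCGC), runs one-step gap-bridging
repair, and shows the full predicted spectrum with and without the
template.
"""

from exactsim import exact_bridge_repair, simulate_spectrum
from exactsim.synthetic import fixtures

fix = fixtures("F_NOTI")
product = exact_bridge_repair(fix.locus, fix.junction, fix.oligo)
print(f"reference ({len(fix.locus)} nt), cut at {fix.junction} (Cas9, blunt)")
print(f"precise product: net indel {product.net_indel:+d} bp, pathway {product.pathway}")
print(f"NotI site present: {'GCGGCCGC' in product.seq}")

with_oligo = simulate_spectrum(fix.locus, guide=fix.guide, oligo=fix.oligo, seed=1)
without = simulate_spectrum(fix.locus, guide=fix.guide, seed=1)
print("\nclass frequencies with template:   ", {
    k: round(v, 4) for k, v in with_oligo.class_frequencies().items()
})
print("class frequencies without template:", {
    k: round(v, 4) for k, v in without.class_frequencies().items()
})
print("\nWithout a template every molecule resolves through error-prone end")
print("joining; with it, most of the spectrum is the programmed +8 insertion.")
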