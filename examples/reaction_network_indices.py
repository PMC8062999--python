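"""Structural (deficiency) indices of the titration reaction networks.

Builds the canonical mass-action network for 1-3 binding sites and
reports complexes, linkage classes, stoichiometric rank and deficiency.
"""

from mirswitch import build_network, deficiency

for n in (1, 2, 3):
    rep = deficiency(build_network(n))
    print(
        f"{n}-site circuit: {rep.n_complexes} complexes, "
        f"{rep.n_linkage_classes} linkage class(es), rank {rep.stoich_rank}, "
        f"deficiency {rep.deficiency}, weakly reversible: {rep.weakly_reversible}"
    )
print(
    "Interpretation: the deficiency delta = n - l - s bounds a mass-action\n"
    "network's capacity for multistationarity irrespective of rate constants.\n"
    "Writing complex degradation as recycling steps links the degradation\n"
    "products back into the synthesis/decay linkage class, so the canonical\n"
    "bookkeeping here yields a single linkage class; other notations of the\n"
    "same chemistry can report different indices."
)
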