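"""Heptad registers, g<->e' pairs and the dimerization call.

Constructs one zipper with an attractive first-heptad pair (favouring
homodimerization) and one with only repulsive complete pairs
(heterodimerizing), and prints the per-heptad profile for each.
"""

import bzipfam as bz

rules = bz.default_rule_table()


def show(pid, zipper):
    protein = bz.ProteinRecord(pid, "N" + "F" * 7 + "R" + "F" * 9 + zipper)
    domain = bz.find_domain(protein, rules)
    profile = bz.build_profile(domain, protein)
    print(f"\n{pid}: {len(profile.heptads)} heptads -> {profile.dimer_call}")
    print(f"  signature {profile.signature}")
    for pair in profile.pairs:
        print(f"  heptad {pair.heptad_index}: g={pair.g_residue} e'={pair.e_residue}"
              f"  {pair.completeness}"
              f"{' / ' + pair.pair_class if pair.pair_class else ''}")


# g of heptad 1 = E (acidic), e of heptad 2 = K (basic): +/- attractive
show("homodimerizer", "LQAEAVY" + "LKASAVY" + "LSASAVY")
# both complete pairs like-charged: repulsive only
show("heterodimerizer", "LQAEAVY" + "LDAKAVY" + "LRASAVY")

# An attractive g<->e' salt bridge in the first heptad with no repulsive
# pair anywhere predicts homodimerization; a zipper whose complete pairs
# are all repulsive is predicted to need a heterodimer partner.
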