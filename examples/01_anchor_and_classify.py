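"""Anchor a bZIP domain and classify its DNA-binding group.

Builds three small proteins around the invariant N-x7-R/K-x9 basic
motif — one canonical, one with the group-IX Lys substitution at -18,
one with the group-XI Ile at -10 — then scans, numbers and classifies
each.
"""

import bzipfam as bz

rules = bz.default_rule_table()

proteins = [
    bz.ProteinRecord("canonical", "MSGYF" + "N" + "F" * 7 + "R" + "F" * 9 + "LAAVSTQ" * 4),
    bz.ProteinRecord("lys_at_-18", "MSGYF" + "K" + "F" * 7 + "R" + "F" * 9 + "LAAVSTQ" * 4),
    bz.ProteinRecord("ile_at_-10", "MSGYF" + "N" + "F" * 7 + "I" + "F" * 9 + "LAAVSTQ" * 4),
]

print(f"{'protein':<12} {'anchor':<12} {'zipper':>6}  group  anomalies")
for protein in proteins:
    domain = bz.find_domain(protein, rules)
    call = bz.classify_binding_group(domain, protein, rules)
    anchor = f"{domain.asn_index}/{domain.basic_residue_index}/{domain.first_leu_index}"
    anomalies = ",".join(f"{pos}:{obs}" for pos, _, obs in call.anomalies) or "-"
    print(f"{protein.id:<12} {anchor:<12} {domain.zipper_length:>6}  {call.group:<5} {anomalies}")

# The anchor triple is the 0-based index of the residues at positions
# -18, -10 and +1; the zipper length counts residues from +1 to the
# first helix breaker (or sequence end).  The Lys and Ile substitutions
# route the proteins to groups IX and XI and are reported as anomalies
# against the canonical Asn/Arg anchor.
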