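# Default binding-group rule table.
#
# Positions are the family's signed basic/hinge numbering (-18..-1; the
# anchor Asn is -18, the invariant Arg/Lys -10).  Rules are tried in the
# order listed; the first group whose constraints all hold wins, so the
# groups defined by characteristic deviations come first and group I is
# the generic Asn/Arg fallback.
#
# Only the group XI rule (hydrophobic Ile at -10 instead of Arg/Lys) and
# the group IX rule (Lys substitution at -18) are family-characterized;
# the rules for the remaining nine groups are synthetic stand-ins keyed
# on hinge position -4 so that all eleven labels are assignable.  Edit
# or replace this file for a family with a characterized rule set.
groups:
  - label: XI
    rules:
      -10: I
  - label: IX
    rules:
      -18: K
  - label: II
    rules: {-18: N, -10: KR, -4: Q}
  - label: III
    rules: {-18: N, -10: KR, -4: S}
  - label: IV
    rules: {-18: N, -10: KR, -4: T}
  - label: V
    rules: {-18: N, -10: KR, -4: A}
  - label: VI
    rules: {-18: N, -10: KR, -4: G}
  - label: VII
    rules: {-18: N, -10: KR, -4: V}
  - label: VIII
    rules: {-18: N, -10: KR, -4: M}
  - label: X
    rules: {-18: N, -10: KR, -4: W}
  - label: I
    rules: {-18: N, -10: KR}

residue_classes:
  hydrophobic: LIVFM
  acidic: DE
  basic: KR          # histidine uncharged by default; add H here to treat it as basic
  breakers: P        # alpha-helix breakers terminating the zipper; PG also common
  initiators: L      # zipper-initiating residue(s) at +1; widen to LIVFM for degenerate zippers
  neg18_substitutes: KR   # tolerated in place of Asn at -18 (group IX Lys)
  neg10_substitutes: I    # tolerated in place of Arg/Lys at -10 (group XI Ile)
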