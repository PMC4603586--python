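# Methods

## Domain anchoring and numbering

A candidate anchor is any sequence index *i* with an accepted −18
residue at *i*, an accepted −10 residue at *i*+8 and a zipper initiator
at *i*+18 (the N-x₇-R/K-x₉ spacing; the nine hinge residues separate
the basic residue from the zipper). Accepted sets are data in the rule
table: −18 is Asn plus configurable substitutes (default {K, R} — Lys
is the characterized group-IX substitution, and some families number an
Arg there), −10 is {R, K} plus substitutes (default {I}, the group-XI
deviation), and the initiator defaults to {L} (widen to {L,I,V,F,M} for
degenerate zippers whose first d residue is another bulky hydrophobic).
The zipper extends from +1 to the residue before the first α-helix
breaker; the breaker set defaults to {P} with {P,G} selectable, since
"helix breaker" has no single community definition and Gly is only a
weak breaker. When several candidates exist the one with the longest
zipper wins, ties to the leftmost anchor — the zipper is the defining
C-terminal feature, and the rule is deterministic and testable. The
numbering maps −18…−1 over the basic/hinge block and +1 onward over the
zipper, with no position 0; it is a bijection over the covered span.

## Binding groups

Groups I–XI are an ordered rule list; each rule is a set of (signed
position in −18…−1, allowed residues) constraints and the first fully
satisfied rule wins. Precedence therefore puts deviation-defined groups
(XI: Ile at −10; IX: Lys at −18) before the generic Asn/Arg fallback.
Only those two rules are family-characterized; the shipped defaults for
the other nine groups key on hinge position −4 and are explicitly
stand-ins so that all eleven labels are exercisable — the table is data
(YAML), not code, and real studies should load their own. Deviations of
the −18/−10 residues from {N}/{R,K} are always reported as anomalies
regardless of which rule matched. Unknown residues (X) match no rule
constraint and no residue class anywhere in the package.

## Zipper registers and g↔e′ pairs

Default register phase puts +1 at d (canonical zipper leucines occupy
d), giving the standard g→e′ i→i+5 spacing; an integer register offset
rotates the phase for families numbered differently, and every
downstream statistic honors it. Heptad *n* spans positions
7(*n*−1)+1…7*n*; a truncated final heptad is retained with only the
registers it contains and contributes to per-register composition only
for those. Charged = acidic {D,E} ∪ basic {K,R}; His is uncharged by
default (its protonation is pH-dependent) and can be moved to the basic
set by config. A heptad's g pairs with the following heptad's e; a
trailing g with no following e is excluded from every pair category
rather than counted as incomplete, since the partner position simply
does not exist.

## Dimerization and subfamilies

Attractive = the two mixed-charge complete classes, repulsive = the two
like-charge classes; incomplete pairs are neutral for the call (a
single charge contributes little to homodimer stability but can be
complemented in a heterodimer). The call is: homodimer iff an
attractive pair exists at heptad 1 and no repulsive pair exists
anywhere; heterodimer iff at least one complete pair exists and all
complete pairs are repulsive; both otherwise. Subfamilies partition
proteins by an exact signature — heptad count plus the ordered
per-heptad pair-class codes — labelled BZ1, BZ2, … in lexicographic
signature order so labels are stable across runs. This signature
partition is a documented stand-in for curated subfamily tables: it
reproduces the qualitative behaviors (attractive-first/no-repulsion
subfamilies call homodimer, repulsive-only subfamilies call
heterodimer) without claiming to reproduce any particular published
membership list, whose exact criteria are not fully specified by
rule-style definitions.

## Intron phases and patterns

Phases derive from CDS segment junctions in transcript orientation:
cumulative coding nucleotides mod 3 gives P0/P1/P2, the codon
containing (P1/P2) or following (P0) the splice gives the protein
position, and P1/P2 introns record the interrupted residue. Only CDS
segments define introns — introns within UTR-only exons are invisible
by construction, which matches how domain-window analyses are drawn.
An intron belongs to the basic/hinge window iff its codon's signed
position is in −18…−1; the +1 codon is excluded. Patterns: f = empty
window (the intronless flag is reported separately, because f also
contains genes spliced only outside the window); c = two P0 window
introns; d/e = one P2 intron interrupting Gln/Arg; one P0 intron splits
into a (basic sub-window, default −18…−11) vs b (hinge, −10…−1) — the
a/b boundary is configurable data because the exact published split is
diagram-defined rather than stated. Anything else (notably P1 window
introns) is reported as unclassified with reasons, never forced into a
pattern. With annotated alternative transcripts the longest CDS per
gene is kept.

## Tandem clusters and composition

No community-standard tandem rule exists, so both common conventions
are implemented: with a full gene census, two family genes chain when
at most `max_intervening` (default 1) non-family genes lie between
them; with family-only input, when their genomic gap is at most
`max_gap_bp` (default 100 kb). Clusters are maximal chains of ≥2.
Segmental-duplication blocks are never computed — they are consumed as
a 4-column interval table from external synteny tools and genes are
mapped into them by containment only. Composition tables offer two
denominators: `all_members` (every protein counts at every heptad,
matching survey-style percentages over the whole family) and
`members_with_heptad` (only proteins reaching that heptad), which is
never smaller per heptad; both are exposed because published per-heptad
percentages are often ambiguous about the denominator.

## Expression

Replicates are averaged on the Ct scale before differencing (the
within-sample technical mean is the quantity the ΔCt formula expects);
ΔCt = mean Ct(gene) − mean Ct(reference) per sample, ΔΔCt subtracts the
calibrator's ΔCt, fold = 2^−ΔΔCt, so the calibrator fold is exactly 1
by construction. Clustering operates on log2 folds (the scale heatmaps
display) with distance 1 − Pearson r and average linkage; rows are
sorted by gene id first so ties resolve lexicographically and reruns
are identical. Zero-variance profiles have no defined correlation and
are placed at the maximum distance 2.0 from every profile; a matrix
with fewer than two non-constant rows is an error.

## Synthetic families

The generator is the package's study bench: each protein plan fixes the
binding group, the heptad count (3–9, the spread observed in plant bZIP
surveys), the per-boundary g↔e′ pair classes, Asn-at-a heptads,
optional partial final heptad, breaker/tail placement and an intron
plan derived from a target pattern (including degenerate P1 plans that
must be flagged, not misclassified). Background residues are drawn from
an alphabet that excludes N/K/R/I and all charged residues, so no
accidental anchor or charge can arise outside the planted positions; a
rejection loop additionally re-draws any draft whose scan finds
anything but the single planted anchor. Back-translation uses one fixed
codon per amino acid — reproducibility over codon-usage realism — and
gene models place cluster members 2–20 kb apart versus ≥150 kb
otherwise, so the planted tandem layout is unambiguous under the
default gap rule. Ct tables use 3 replicates with Gaussian noise of
0.15 cycles (typical qRT-PCR technical spread) around planted log2
fold effects drawn from N(0, 2). Everything derives from one seed and
outputs are byte-identical across reruns.

What the generator does **not** emulate: phylogenetic relatedness
between family members, codon-usage bias, UTRs and alternative
transcripts, sequencing/annotation errors, or amplification-efficiency
deviations from the ideal doubling assumed by 2^−ΔΔCt. Passing recovery
tests therefore demonstrates the correctness of the rule arithmetic on
well-formed inputs, not robustness to noisy annotation.

## Problem sizes and numerics

The acceptance run uses a 200-protein mixed-plan family, 100 decoys, a
69-protein/24-signature family for the partition check, 1,000 random
gene models against the codon-walk oracle, the exhaustive 400-pair
truth table under both charge conventions, and ten random 10×6
matrices against the naive O(n³) linkage oracle — sizes at which every
check is exact and the whole run completes in seconds. Pearson
distances are clipped to [0, 2] to absorb floating-point drift in the
correlation; all other comparisons are exact integer or string
equality.
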