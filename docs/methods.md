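# Methods

## Motif model

An NR DBD is modelled as two zinc-finger modules with exact chelator
spacings: CI = `C-X2-C-X13-C-X2-C` (21 residues) and CII =
`C-X5-C-X9-C-X2-C` (20 residues).  Spacer positions accept any amino acid
including the ambiguity code X; chelator positions accept only C (or H at
the second CII chelator when the CHC2 variant is enabled), never X.  A
configuration option widens CI's inner run to a range
(`ci_inner_min`/`ci_inner_max`); the default is the canonical 13 because
the motif definition states exact spacings and widening multiplies false
positives.

All pattern matches at all positions are reported, overlaps included.
Assembly pairs each CI, left to right, with the nearest downstream CII
whose linker gap lies in `[gap_min, gap_max]` (default 6–40 residues);
paired fingers are consumed and assembled DBD spans never overlap.  The
wide upper bound accommodates HR96b-style DBDs whose mature protein keeps
an extra exon between the P-box and D-box.  Because each CI's feasible
CIIs form a window that moves monotonically with the CI, this greedy
matching attains the maximum number of disjoint pairs (verified against
an exhaustive pairing oracle in the tests).  Unpaired fingers are reported
as partial hits and excluded from complement totals by default
(`count_partial_hits`), since nothing in the complement statements
indicates single-finger fragments were counted as genes.

The P-box is the 10-residue window anchored at the third CI chelator (its
first and fourth residues are themselves the last two CI cysteines);
catalogue patterns of length 5–10 match as substrings of that window, so
the 5-/6-/10-mer forms in common use are all honoured, with the longest
match taking precedence.  The D-box is the five residues between the first
two CII chelators.  Coordinates are 0-based half-open throughout;
identifiers are preserved verbatim.

## Splice-aware reconstruction

Given genomic sequence, the reconstructor enumerates splicings with up to
two introns where every intron begins `GT`, ends `AG`, has length in
`[30, 20000]` nt, and lands on a catalogued junction (an amino-acid column
within the DBD plus codon phase) within ±1 column.  The search is anchored
on a complete CI found in a direct frame translation — valid for the
shipped catalogue, whose junctions all lie downstream of CI, matching
where NR DBD introns actually fall (between the P-box and D-box regions or
inside CII).  Donor positions are predicted from the junction catalogue;
for each donor only the nearest `max_acceptors_per_donor` (40) in-bounds
acceptors are tried, a deterministic cap that keeps the enumeration
desk-scale.  Candidate DBDs containing stop codons are rejected.

Ranking is (smallest total junction deviation, fewest introns, longest
DBD, coordinates).  The source material does not say how competing
GT-AG-consistent splicings were disambiguated; deviation-first is this
package's convention — prefer the splicing that needs no tolerance — and
the reverse-complement search is off by default (`six_frame`).

## Classification

Classification combines three signals with a fixed precedence:

1. **P-box catalogue.**  The core file carries only published diagnostics
   (ESCKG→NR5, CDGCRG→NHR236, EACKA→ERR, CEGCKGFFRR→NR1-typical,
   CEGCKGFFKR→{RXR,TR4,NR4A} ambiguous-typical, and four known divergent
   10-mers).  A documented, user-editable extension file adds canonical
   boxes for further groups (HNF4, TLX, PNR, DSF, fax-1, Coup-TF, GCNF);
   these are package conventions, deliberately kept out of the core file.
2. **Nearest reference.**  The query DBD is aligned to each labelled
   reference by forcing the eight chelator columns into register and
   right-padding the intervening segments; the p-distance ignores gapped
   columns (pairs sharing <20 comparable columns get distance 1.0 with a
   warning).  A reference within 0.35 p-distance proposes its group.  The
   0.35 default approximates the within-group identity the underlying
   tree-based assignments imply; it is configurable.
3. **Conflict rule.**  The nearest-reference group must be consistent with
   the P-box candidates (same group, same family base, or same
   subfamily); on conflict the P-box wins, mirroring the practice of
   trusting a diagnostic P-box over a weakly supported tree placement.
   Tandem-DBD (2DBD) architecture is itself the subfamily diagnostic: for
   those genes the group comes from the second, more conserved DBD's
   nearest 2DBD reference and the P-box does not constrain it.

A gene is *divergent* when its P-box is atypical, or when a typical P-box
resolves neither a group nor a unique subfamily (the CEGCKGFFKR case,
which spans NR2 and NR4).  A typical box with a resolvable subfamily but
no group (e.g. an ESCKG gene far from every reference) is *not* divergent.
Complement rows count one gene per record with ≥1 full DBD; divergent
genes fall into a `divergent` bin mirroring the complement table's
"Other" row.

## Gain/loss model

Each ortholog group evolves under Dollo parsimony: one gain (on the edge
above the most recent common ancestor of all carriers, with a molluscan
outgroup placed as a direct child of the root so pre-flatworm origins are
recoverable) and a minimal set of losses (one per maximal carrier-free
subtree below the gain).  Loss minimality and exact leaf-state
reproduction are verified against an exhaustive assignment oracle for all
presence patterns on trees of up to six leaves.  The class-level analysis
collapses species to five flatworm lineages (M. lignano, S. mediterranea,
Monogenea, Cestoda, Trematoda) plus the outgroup, the resolution at which
the gain/loss narrative is framed; the divergent/unassigned bins are
lineage-specific inventions rather than ortholog groups and are excluded.

The curated ancestral fixture records the published 24-group ancestor
verbatim, along with per-branch events transcribed from the running text.
Two of those groups (NR1b, Coup-TFII) are elsewhere placed as originating
inside the tree, so strict Dollo reconstructs a 22-group ancestor; the
pipeline reports the machine-readable diff and the event-replay comparison
instead of asserting agreement.  The outgroup presence vector is
transcribed where stated (HR96d, NHR236, 2DBDg, ERR explicitly have
non-flatworm members) and otherwise set to present for groups known
outside flatworms; flatworm-specific paralog groups are outgroup-absent.

## Synthetic data

The generator emulates the pipeline's three input kinds with ground truth.

*Proteins.*  A DBD is realised as CI + 9-residue linker + CII (50
residues) with the designed P-box, D-box and optional CHC2 substitution;
flanks and spacers are drawn from an alphabet without C or H, so no
spurious chelator can arise, and zero-DBD decoys are verified pattern-free
by an independent regex matcher.  Point mutations never touch chelator,
P-box or D-box positions unless requested.

*Loci.*  Coding sequence is back-translation with a fixed one-codon-per-
amino-acid table; introns are inserted at the designed junction/phase.
Intron interiors are G-free (hence free of internal GT/AG) and carry a
stop codon every five bases at a period coprime to 3, so every reading
frame is disrupted within 15 nt.  This makes the designed splicing the
unique GT-AG-consistent reading — which is what round-trip tests of the
reconstructor require — at the cost of realism: real introns contain
internal AG/GT sites whose resolution needs branch-point and splice-site
models beyond the dinucleotide rule.  Passing round-trip tests therefore
demonstrates correct enumeration and ranking, not splice-site prediction.

*Histories.*  Single-gain/multiple-loss evolution on a known tree with
per-edge loss probability and an event log sufficient for exact replay.

*The survey stand-in.*  The 33-species survey ships as rosters (species ×
group counts, with named atypical P-boxes for the divergent genes)
realised into sequences: every gene is its group's synthetic reference DBD
plus 2+k point mutations (k the paralog index), parasitic HR96b genes get
the CHC2 substitution, divergent genes get independent random DBDs with
their documented boxes, and 2DBD genes carry a generic first DBD
(CEACKK-type P-box) plus the group reference as second DBD.  References
for different groups are mutually ~0.5 p-distance apart while within-group
queries stay below 0.1, so group recovery is exact by construction.  What
passing the survey tests shows is that the pipeline's rules reproduce the
published complement arithmetic from sequences satisfying the stated
motif/P-box/architecture properties — not that it would classify the
authors' real sequences identically.

## Numerical and reproducibility choices

Neighbor joining breaks Q-criterion ties by lowest creation-order index
pair; negative branch lengths are clamped to zero with the deficit moved
to the sibling so cherry length sums are preserved.  All generators and
the survey are deterministic under a seed; derived seeds stay below 2^31.
Analysis problem sizes (50 × 10-kaa oracle sequences, a 500-protein
scanner panel, 200 splice loci, 30 NJ matrices, 100 monophyly trees, 200
gain/loss replicates per loss rate) were chosen as the smallest sets that
exercise every code path with comfortable margins; the full suite runs in
well under a minute.

## Known limitations

Homology search, LBD analysis, Bayesian/ML tree inference and bootstrap
support are out of scope; externally inferred trees can be read as Newick
for monophyly checks, but NJ co-clustering is boolean evidence, never a
posterior.  The splice reconstructor assumes CI is encoded in one exon.
The anchor alignment is exact only because NR DBDs share the eight
chelators; it is not a general aligner.  Real-genome performance depends
on inputs this package does not model (assembly quality, gene fragmentation,
unannotated non-canonical splice sites).
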