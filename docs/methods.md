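# Methods

## Data model

The mapping is a single Darwin Core Taxon style table (`taxonID`,
`parentNameUsageID`, `scientificName`, `taxonRank`, `datasetName`,
`conceptNote`) holding three layers:

1. **Switchboard** — one record per fine-grained taxon concept, at the
   finest granularity any base authority distinguishes. Concepts carry a
   human label and an optional complex id in `conceptNote`
   (`complex=…; label=…`).
2. **Base lists** — authoritative treatments. Each base record
   ("holder") has exactly one switchboard parent. A base name that
   subsumes several concepts (e.g. a wide species containing several
   subtaxa) is duplicated into one holder per concept. Holder
   duplication is what lets a program that splits more finely than its
   authority keep its granularity: each program concept maps to a
   distinct holder even when the holder names are identical.
3. **Program lists** — each program record points at one holder in the
   program's declared base. A program name covering several concepts
   appears on several rows, one per holder link.

Roles and program→base assignments are derived from the parent chains
themselves (base records point at the switchboard; a program's records
all point into exactly one base) and checked by validation, which also
rejects dangling parents, cycles, and duplicate (name, parent) links.

### Monitored vs. subsumed links

Each program→holder link is typed:

* **monitored** — the program collects data for the concept (it occurs
  in the program's area);
* **subsumed** — the name, as the program uses it, *circumscribes* the
  concept, but no local data exist (serialized as a leading `subsumed`
  token in `conceptNote`).

This split is the central design decision. Translation is asymmetric in
a way a single link type cannot express: a program applying a wide
species concept can meaningfully *receive* data for any subsumed member
(its concept covers them), but can only *donate* data for the members it
actually monitors. Concretely, in the bundled azure-complex fixture,
Iowa's wide "C. ladon" receives a multiple match (its request fans out
to the Cascades program's *lucia* and *echo*), while the Cascades
program requesting *lucia* from Iowa correctly receives Zero — Iowa has
no *lucia* data. With monitored links alone one of the two cells is
wrong, whichever convention is chosen.

`concepts_of()` returns the monitored closure of a name;
`circumscription_of()` returns the full closure.

## Translation and classification

For a request *(receiver A, name x, donor B)*:

* **R** = circumscription of *x* at *A*; **Mₓ** = monitored set of *x*.
* **Candidates** = donor names *y* whose *monitored* set *M_y*
  intersects R (found by the ascend/descend walk over the parent
  chains, restricted to B's declared base).
* Classification:
  1. no candidates → **Zero** ("There is no match in this list (species
     presumed absent)").
  2. a sole candidate with extra data (*M_y ⊄ R*): the donor lumps the
     requested unit with other taxa. If the receiver's *other* names
     monitor all the extra concepts → **CM+** with the required sibling
     list; otherwise → **Zero** — the receiver cannot rebuild the
     donor's pooled unit from its own surveyed taxa, so the donor's data
     are unusable for it. (A lump candidate alongside other candidates
     is a curation error.)
  3. two or more candidates (all within R) → **MM**, names sorted.
  4. a sole within-candidate *y* is *compatible* when it shares
     monitored data with *x* (*M_y ∩ Mₓ ≠ ∅*) or its own
     circumscription lies inside the request (*C_y ⊆ R*); an
     incompatible sole candidate → **Zero**. A compatible candidate is
     **PM** when the canonical names are equal *and* the
     circumscriptions are identical, else **CM**.

Rule 4's compatibility test is what distinguishes two donors with
identical data but different name usages: a donor whose name reaches
beyond the receiver's request (and shares no data with the receiver's
own monitoring) is treated as presumed-absent rather than silently
equated. The PM test compares circumscriptions, not just monitored
sets, so two programs using the same name string for different concept
breadths score CM, not PM.

Subspecies-rank requests need no special casing: a trinomial resolves
through its holder links like any other name, and meets a donor's
species-level name at whatever concept granularity the links encode.

### Flags

* **Asymmetry** — for each returned donor name the reverse request is
  run; if the match *kind* differs (kinds: single = PM/CM, multiple,
  lump, zero), an asymmetry flag is attached. PM vs CM is not an
  asymmetry: the difference is purely nomenclatural.
* **Complexity** — attached to every CM+ (combinability warning); to any
  result whose receiver or candidate records carry a curated `assess`
  marker; and to a Zero against a donor whose treatment of the complex
  is itself contested (spurious-zero risk). The `assess` markers are
  curation inputs, not derived quantities: which interpretations are
  "contested" is a judgement the curators record per record in
  `conceptNote`, and the flag text is drawn from those notes.

## The azure-complex fixture

Seven switchboard concepts (*ladon*, *neglecta*, *lucia*, *echo*,
*humulus*, plus *serotina* and *idella*, which no program's area
reaches); three bases (NABA: one wide *C. ladon* duplicated into five
holders; Opler & Warren: five full species; Pelham: the two western
species the Pelham-based programs need); ten programs. The program
links are curated: wide-concept programs carry subsumed links to the
western segregates, Ohio splits *neglecta* out, three programs use an
explicit *ladon/neglecta* conglomerate, and Orange County's trinomial
"C. ladon echo" monitors *echo* with a curated wider circumscription
(*ladon*, *lucia* subsumed). All records except MPG's and Orange
County's — the two programs whose single local taxon is unambiguous —
carry the `assess` marker. The expected integration matrix (14 receiver
taxa × 10 donors, 126 off-diagonal cells) is shipped both in code and as
CSV and is reproduced cell-for-cell, codes and flags, by the translator.

One caveat documented rather than resolved: the classification above
reproduces the curated matrix exactly, but the strong lump/split duality
("every MM mirrors to CM+ per returned name") holds only when the MM's
donor names lie within the receiver's *monitored* set; an MM produced by
a wide nomenclatural circumscription mirrors to Zero (no donor-side
data). The fixture tests assert duality in exactly that scope; on
synthetic networks, where circumscription equals the monitored set by
construction, the strong form holds and is tested over 1,000 networks.

## Checklist alignment (diff engine)

Pairing order: exact canonical match → curated pairs → heuristics.
Heuristics propose: spelling variants (L) when epithets are within edit
distance 2 *and* share their first two characters (computed with edlib);
genus swaps (G) on a shared epithet; conglomerates (C) when a slash
name's components match two names opposite; subspecies
promotion/use patterns (S candidates). Synonym-type S deviations are
deliberately *not* guessed from strings — synonymy is curatorial
knowledge (in the motivating study it was resolved by asking the program
directors) — so without a curation entry such records stay unmatched.
Ambiguous ties (two equally good candidates) are reported, never chosen
silently. Subfamily (F) deviations are computed only when both lists
carry subfamily headers, counted per descendant species, and excluded
from species-level summaries, since program data integration hangs off
lower-level taxonomy. Percentages are reported against the larger list's
species count, rounded to one decimal place.

## Synthetic networks

The generator emulates the observed structure of the real network: a
concept pool split across genera, several bases that may lump eligible
same-genus concept pairs (duplicated holders), and programs derived from
an assigned base with per-name deviations injected at fixed rates.
Defaults (12 concepts, 2 bases, 4 programs, G/S/L ≈ 1%, C ≈ 0.5%,
U ≈ 1%, lump rate 0.1) mirror the few-percent deviation totals observed
between real program lists and their authorities. Design choices that
make ground truth exact:

* epithets come from a fixed syllable alphabet and are globally unique;
  spelling edits duplicate the final character (distance 1, first two
  characters preserved) while synonym epithets differ in their first
  syllable — the two injections can never be confused by the aligner;
* lumpable pairs are fixed globally before any list is derived, so any
  two lists' units are nested or disjoint, never partially overlapping
  two different lumps (the mixed-lump curation error cannot arise);
* every injection is recorded, and expected match types are derived by
  direct concept-set comparison (`oracle_match`) on the generator's own
  bookkeeping — independent of the mapping graph the translator walks.

What the generator does **not** emulate: geographic ranges (occurrence
is encoded only through which concepts a program monitors), subsumed
wide-concept links (synthetic circumscription = monitored set),
subfamily structure, and curated complexity markers. Passing synthetic
tests therefore demonstrates the correctness of the traversal,
classification, alignment and round-trip machinery under known ground
truth — not the fidelity of any particular real-world curation, which
is what the curated fixture covers.

## Numerical and procedural choices

* All randomness flows through one `random.Random(seed)`; same seed,
  byte-identical output files. Iteration orders are insertion/sorted
  orders throughout; MM donor names are returned sorted.
* Name matching is case-insensitive and whitespace-normalized; stored
  strings preserve the source's sanctioned spelling. Abbreviated genera
  ("C. ladon") are expanded against the containing list's genus context
  at load time; bare abbreviations are a parse error.
* An unknown receiver name is a hard error (exit 2 on the CLI); Zero is
  a valid answer and exits 0.
* Edit distances come from edlib; the test suite checks them against an
  independent dynamic-programming oracle and the metric axioms.
* The property suite runs 1,000 synthetic networks (10 concepts, 2
  bases, 3 programs each) for translation/duality checks, with deeper
  round-trip and alignment-recovery checks on every 100th network —
  sizes chosen to exercise every code path many times while keeping the
  default test run fast.

## Limitations

* Full-catalogue statistics (hundreds of species across four complete
  base treatments and ten program lists) require the complete
  third-party checklists, which are not bundled; the
  `taxoswitch.supplementary` loaders recompute them when those files are
  supplied locally under `data/supplementary/`.
* Third-party receivers (a user with their own taxonomy, not one of the
  programs) are out of scope; requests are always program-to-program.
* The mapping encodes occurrence only through curated links; it does not
  reason over range polygons, and post-publication taxonomic revisions
  enter only as curation updates (or `assess` flags), not automatically.
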