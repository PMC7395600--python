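# taxoswitch

Taxon-concept curation and translation across species-monitoring programs.

## The problem

Regional monitoring programs (the motivating case: North American
butterfly programs running Pollard-walk transects) each keep their own
stable species checklist, interpreted against different authoritative
treatments. Because authorities lump and split taxa differently, the
same name can denote different taxon concepts in different programs —
and different names the same concept. Naively joining count data by name
string silently merges incompatible concepts and manufactures spurious
zeros, which bias any cross-program analysis.

`taxoswitch` implements a curation system that makes checklists
interoperable without forcing any program to change its list:

* every program name is linked, through a holder record in the program's
  declared **base authority** (e.g. NABA, Opler & Warren, Pelham), to a
  master **switchboard** of fine-grained taxon concepts, using Darwin
  Core Taxon parent/child chains (`taxonID` / `parentNameUsageID`);
* a base name subsuming several concepts is **duplicated** into one
  holder per concept, so a program that splits more finely than its
  authority keeps its granularity;
* each program→holder link is either **monitored** (the program's data
  actually cover that concept) or **subsumed** (the name's nomenclatural
  breadth only — the taxon does not fly in the program's area).

## The translation algorithm

A request is a triple *(receiver program, taxon, donor program)*. The
algorithm ascends the parent chain from the receiver's records to the
switchboard concept set *R* (the name's circumscription), then descends
through the donor's base list to the donor records holding data for any
concept in *R*, and classifies the outcome:

| code | meaning |
|------|---------|
| `PM` | perfect match — identical name and identical circumscription |
| `CM` | compatible match — same concept(s), different nomenclature, or a donor unit nested in the receiver's wider concept |
| `MM` | multiple match — the donor splits the receiver's unit; all returned names must be combined |
| `CM+` | the donor lumps the receiver's unit with other taxa; donor data are combinable only together with the listed receiver sibling taxa |
| `Zero` | no donor data fall within the receiver's concept ("species presumed absent") |

Warning flags accompany the codes: an **asymmetry** flag when the
reverse request yields a different kind of match, and **complexity**
flags for lump combinability and for records whose concept
interpretation the curators marked as contested.

## Worked example

The bundled fixture encodes the *Celastrina ladon* (spring azure)
complex: seven concepts, three base authorities, ten programs. Iowa
follows NABA's wide *C. ladon* (its data pool the *ladon* and
*neglecta* subtaxa); the Cascades program follows Pelham and records
*C. lucia* and *C. echo* as separate species:

```
$ taxoswitch translate --receiver Iowa --taxon "Celastrina ladon" --donor Cascades
Iowa: Celastrina ladon -> Cascades: Celastrina echo, Celastrina lucia [MM]
flag (complexity): one name collects both local subtaxa under the authority's
  wide species concept; lucia/echo segregates are difficult to distinguish near
  their range contact
flag (asymmetry): reverse request (Cascades: Celastrina echo -> Iowa) yields
  Zero, not MM; the match is not symmetrical
```

Read: from Iowa's (wide) concept of *C. ladon*, the Cascades data for
*C. echo* and *C. lucia* are both relevant and must be combined (`MM`);
but a Cascades user asking for *C. echo* from Iowa gets `Zero` — Iowa
holds no data for that concept — so the pair is flagged as asymmetric.

The whole complex at once:

```
$ taxoswitch matrix --complex Celastrina-ladon-complex
receiver / donor               IL     IA     MI     OH     TN     FL     CAS    MPG    CO     OC
IL: Celastrina ladon/neglecta  X      CM*    PM*    MM*    PM*    MM*    MM*    CM*    MM*    CM*
IA: Celastrina ladon           CM*    X      CM*    MM*    CM*    MM*    MM*    CM*    MM*    CM*
...
```

(`*` marks flagged cells; only the two requests between Orange County
and MPG — the two programs monitoring the same single unambiguous
taxon — carry no flag.)

Other commands: `taxoswitch validate` (structural invariants of a
mapping file), `taxoswitch diff` (align two checklist CSVs and count
deviations by type G/S/L/C/U), `taxoswitch fixture --synthetic`
(generate a seeded synthetic network with known ground truth).

## Layout

* `taxoswitch.names` — scientific-name parsing (binomials, trinomials,
  slash conglomerates), canonical forms, epithet edit distance
* `taxoswitch.core` / `taxoswitch.checklist_io` — Darwin-Core-style
  mapping-file model and CSV I/O
* `taxoswitch.switchboard` — concept graph: holders, closures, validation
* `taxoswitch.diff_engine` — checklist alignment and deviation typing
* `taxoswitch.translator` — the ascend/descend algorithm and match
  classification
* `taxoswitch.matrix` — integration matrices and the comparison harness
* `taxoswitch.fixtures` — the curated azure-complex fixture and the
  synthetic-network generator
* `taxoswitch.supplementary` — full-catalogue alignment statistics (for
  locally supplied complete checklists)

See `docs/methods.md` for the data model, the classification rules and
their rationale, and known limitations.
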