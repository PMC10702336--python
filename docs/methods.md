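# Methods

## Record model and backbone taxonomy

A source record carries its sequence, an ordered raw lineage of
(rank-label, name) pairs, the lowest identification as given, and optional
location metadata (country text; WGS84 decimal coordinates). Only the seven
standard ranks — kingdom, phylum, class, order, family, genus, species —
are ever displayed in the final database; intermediate ranks survive in the
backbone store but are skipped when a lineage is projected.

The backbone store is an SQLite database (in memory or on disk) indexed on
the lowercased canonical name and on (name, rank); the contract is that
query latency is independent of dump order, not a particular engine. Two
dump dialects are imported: a GBIF-backbone-style TSV (taxonID,
parentNameUsageID, acceptedNameUsageID, canonicalName, taxonRank,
taxonomicStatus) and an NCBI-taxdump-style nodes/names pair, where each
names row of class "synonym" becomes its own synonym node pointing at the
scientific-name node. Malformed rows are skipped, logged, and counted in
the import report. Synonym chains are resolved transitively with a depth
guard of 10; a cycle or a dangling accepted-id is a hard error. Name
matching is case-insensitive and exact — no fuzzy matching.

Homonyms (one name string, several taxa) are resolved at lookup time in
three steps: a rank hint, then a context name that must occur in a
candidate's ancestry (during harmonization the record's own higher lineage
supplies the contexts), then a user-supplied homonym list — a 3-column TSV
(name, rank, resolving kingdom), the minimal information that makes
disambiguation deterministic. A name that stays ambiguous is returned with
all candidates; harmonization then treats that rank as unmatched and falls
back to the next higher rank rather than guessing.

## Name cleaning

Digits are erased. Open-nomenclature qualifiers (aff., cf., cff., sp.,
spp., nr., prope, gr., s.l., s.s., indet., ?) are matched case-insensitively
with the trailing period optional; the first qualifier *and everything after
it* is dropped, because an epithet following a qualifier was not a certain
identification ("Apis cf. mellifera" → "Apis"). The qualifier list ships as
an editable data file. Hybrid markers (×) are stripped and logged. The
cleaned output contains only letters, spaces, and hyphens, and cleaning is
idempotent. An empty result is legal and flagged, not an error.

## Harmonization

In mapped mode the cleaned lowest-rank name is looked up first; on a miss
the record's own higher taxa are tried upward until one matches. Actions:
`exact` (accepted match at the lowest name), `synonym_replaced` (synonym
match; the accepted partner supplies the name — with synonyms allowed, the
synonym stays as the displayed species name while the higher ranks still
come from the accepted node, since rank-wise classifiers need congruent
higher ranks), `rank_fallback` (match only at a higher rank; the lineage is
truncated there), and `unmatched` (kept, removable later via the
minimal-rank filter). Record counts are conserved in both modes, and a
record's taxonomic resolution never increases. Unmapped mode projects raw
lineages verbatim (action `passthrough`); source-specific kingdom labels
(GBOL "Animalia", GenBank "Metazoa", BOLD none) are deliberately left
divergent. Names produced by rank fallback are not re-cleaned; fallback
candidates are already cleaned before lookup.

GBFF ORGANISM lineages carry no rank labels; the reader assigns the labels
kingdom–genus positionally (enough for unmapped projection of the fixture
convention where the lineage starts at the kingdom). Mapped harmonization
ignores these labels and walks names, so real-world GBFF lineages that
begin with "Eukaryota" only affect unmapped runs.

The comparison file aggregates one row per distinct (accepted name,
provided name, action) with a count — the reconciliation view of every
renaming the build performed.

## Filters

All filters are pure predicates, so outcomes are order-independent.
Defaults: at most 5 'N' bases (other IUPAC ambiguity codes are counted by a
separate optional bound, not by max_n), length 400–2000 bp (400 bp is a
common floor for usable CO1 fragments; 2000 bp tolerates whole-gene
submissions), no minimal-rank requirement. The translation check accepts a
record when at least one of the three forward frames is stop-free under the
invertebrate mitochondrial code (NCBI table 5, the correct code for animal
CO1); reverse frames are not checked because barcodes are deposited in
coding orientation. Whether a failing record is dropped or only flagged is
configurable; the default is to warn, since a failed in-silico translation
can reflect a reading-frame annotation problem rather than a pseudogene.

Geography: country text expands to {country, continent, realm} via a
gazetteer (a built-in table ships with the package; any TSV can replace
it); coordinates are tested against named polygons (GeoJSON, or rings given
programmatically) with shapely, boundary-inclusive, (lon, lat) WGS84 order
as in shapefile practice. Text and point labels are unioned. While a region
filter is active, records without any usable location are dropped.

## Dereplication

Identity is exact string equality of sequences — no trimming, no substring
matching. For each cluster the member lineages are reconciled by a cascade:
(a) if the distinct lineages form a prefix chain (each agrees with the next
wherever both are filled), the most resolved one wins; (b) otherwise the
lineage with the unique maximum record count wins — "majority" is a
plurality over *full* lineages, never per rank, so no chimeric lineage can
be assembled; (c) a tie on the maximum takes the LCA of the tied lineages.
A majority can therefore beat a minority lineage that is more resolved;
rule (a) only applies when nothing conflicts. The representative is the
lexicographically smallest member id of the winning group, making output
independent of input order.

## Pairwise identity and the THID benchmark

Global Needleman–Wunsch with affine gaps (three-state Gotoh), compiled with
numba. Scores: match +2, mismatch −4, a gap of length L costs 20 + 2L
(open 20, extend 2 per residue including the first) — the documented
defaults of the usual THID benchmark tool. Identity is 100 × matching
columns / alignment columns with terminal gap runs excluded from the
denominator. Because co-optimal alignments can differ in matches and in
terminal-gap placement, ties are broken deterministically: first toward
more matching columns, then toward the aligned (diagonal) state. Identity
is symmetric and independent of input order.

The top-hit search is an exhaustive scan of every reference for every query
— the accept/reject pruning heuristics of the usual tools are intentionally
not reproduced; exact search guarantees the true top hit and is feasible at
the scales this package targets. Hits below the identity floor (default
0.70) are discarded; identity ties between references go to the
lexicographically smallest reference id. Binned identities are rounded
half-up (floor(x + 0.5)). Dense ranks are ascending (fewest hits at 100% →
rank 1) with ties sharing the minimum rank. Cross-coverage subsamples n
sequences per replicate without replacement (seeded NumPy generator, fixed
iteration order over databases for reproducibility) from every other
database, searches them against the target, and reports mean ± SD of hit
counts at the 100/99/98 bins across replicates.

## Synthetic data generator

The generator builds a self-consistent toy world: one animal kingdom with 2
phyla, 3 classes, 4 orders, and species-count-scaled families and genera;
10% of species get a synonym node by default; 2 genus names are duplicated
under a second (plant) kingdom and listed in the homonym file; 5% of
species get a genus absent from the backbone but a real family (forcing
rank fallback); one record carries an entirely fabricated lineage (forcing
unmatched). Records (default 40 BOLD + 30 GenBank + 30 GBOL, 658 bp
sequences) are written in the real dialects — a Biopython-written GBFF with
CO1 CDS features plus one rRNA decoy, a BOLD TSV with a wrong-marker decoy
row, a GBOL CSV with quoted commas and a configurable fraction of missing
order cells. About 10% of names are decorated with open-nomenclature
qualifiers; 5% of records get 8 planted 'N's so the default quality filter
has work to do. Queries are copies of record sequences with exactly k
substitutions at distinct positions (k cycles through 0, 1, 3, 5, 10, 30 by
default), so the expected identity is exactly (L−k)/L and the expected
THID bin is forced. Truth tables record, per record, the provided name,
expected cleaned name, expected action and lineage, expected quality
outcome, and the cluster key; per query, k and the expected bin. Same seed,
same spec → byte-identical files (the GBFF date field is pinned).

What the generator does **not** emulate: phylogenetically realistic
sequence evolution (sequences of different species are independent random
strings, so cross-species identities are far below any sensible floor),
indel-rich queries (substitution-only by construction), misidentified
records, rank-dependent name formatting quirks of the real sources, and
real GBFF lineages that start above the kingdom. Passing tests therefore
demonstrate the correctness of the bookkeeping — parsing, cleaning,
mapping, filtering, clustering, binning — not classification accuracy on
real communities.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full build on datasets of
~100 records of 658 bp (and down to 60 bp for the many-seed invariant
sweeps), 100×100 query/reference alignments for the search-vs-oracle
comparison, and 50 independently seeded generator runs for the conservation
invariants — sizes chosen so the whole suite completes in well under a
minute of alignment work while still exercising every code path. Alignment
scores are integers throughout; identity is computed in double precision
from integer match/column counts, so equality comparisons in tests are
exact up to standard float division. Degenerate inputs: empty sequences are
rejected by the aligner; an empty cleaned name is legal and flagged; an
empty backbone store behaves as the "no backbone" option and forces
unmapped behaviour.

## Known limitations

ESRI shapefile input is not supported (GeoJSON or programmatic rings only).
The GBOL CSV layout varies between releases; the column map is configurable
and the shipped default matches the generator's layout. Rounding of binned
identities is half-up; half-even would shift ties at .5 by one bin.
Unmapped mode performs no cross-source kingdom reconciliation by design.
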