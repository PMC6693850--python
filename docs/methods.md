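# Methods

## Data model and assumptions

The pipeline analyses maternally inherited, non-recombining mitochondrial
protein-coding sequence.  Its unit of analysis is the *haplotype*: a
unique concatenated CDS sequence over the columns that are unambiguous in
every included specimen.  The underlying biological picture is a set of
deeply diverged maternal lineages (main haplogroups), structured into
subgroups, with recent outbreak populations appearing as shallow
radiations of one or two mutations around a founder haplotype.  At this
time depth homoplasy (repeat or back mutation at a site) is rare, which
is what makes integer Hamming distances readable as "numbers of
mutations" and makes median-joining networks nearly tree-like.

## Specimen inclusion and column masking

Specimens enter the analysis when their metadata reports mean read
coverage ≥ 10× and breadth 1.0 (every reference position covered); both
bounds are inclusive and configurable.  Breadth is taken from the
metadata rather than recomputed — read mapping is upstream of this
package.

After concatenating the per-gene alignments (fixed canonical gene order
atp6 … nad6, configurable; results are invariant to it), every column
containing a gap or non-ACGT code in *any* specimen is removed globally.
This makes all pairwise distances integer and mutually comparable, at a
documented cost: two specimens differing only inside masked columns
collapse into one haplotype.  The raw width (gap columns included) is
reported alongside for comparability with alignment-level statistics.

## Minimum spanning and median-joining networks

The minimum spanning network (MSN) is the union of all minimum spanning
trees: distinct distance values are processed in ascending order and at
each level every pair within the level that joins components distinct
*before* the level is added, so equal-weight alternatives all survive.
With ε > 0 the admission window widens to d ≤ level + ε; the default is
ε = 0 (strictest).

Median joining augments the node set with *median vectors*: the
column-wise majority consensus of a triple of sequences.  The
implementation iterates:

1. build the MSN over the current nodes;
2. enumerate candidate medians from u–v–w paths (v adjacent to both);
3. try candidates in ascending connection-cost order
   (d(m,u)+d(m,v)+d(m,w), ties broken lexicographically on sequence) and
   add the first whose inclusion strictly reduces total network length;
4. when no single candidate helps, a bounded two-median lookahead tries
   pairs (m₁, m₂) with m₂ a median of a triple involving m₁ — radiations
   with two unsampled internal ancestors need both before either pays
   off (`pair_escape_limit`, default 30, caps the m₁ candidates
   examined);
5. at convergence, delete every median whose removal does not increase
   total network length.

The deletion rule in step 5 is deliberately length-aware rather than
purely topological: removing a degree-2 median that lies exactly between
its neighbours can still *lengthen* the network when its presence had
suppressed equal-weight tie edges at a higher distance level, so such
medians are kept.  Medians of degree ≤ 1 always shorten on removal and
therefore never survive.

At a three-way-tied column (all three states distinct) the median copies
the state of the lexicographically smallest of the three sequences.  This
replaces the full quasi-median expansion of the original formulation,
which can generate exponentially many vectors; the choice is
deterministic and independent of input order, and is flagged here rather
than in output metadata.

**Verification.**  On 200 seeded clonal-radiation instances (≤ 5 sampled
haplotypes, ≤ 12 sites, every mutation at a fresh column, leaf-biased
sampling so that median vectors are required in roughly half the
instances) the resulting network length equals an exhaustive Steiner
oracle — minimum MSN length over all subsets of the quasi-median closure
— and is never longer than the plain MSN.  These instances mirror the
homoplasy-free regime the pipeline targets.  **Known limitation:** under
heavy homoplasy (i.i.d. random sequences, repeated/back mutation) the
heuristic, like the published algorithm it follows, is not always
Steiner-optimal; in our experiments a few percent of such instances end
one or two mutations above the optimum.

## Haplogroup nomenclature

"Separated by more than T mutations" is implemented as single linkage:
haplotypes are in the same cluster iff a chain connects them with every
consecutive pair at distance ≤ T, so distinct clusters are > T apart by
construction, and this is asserted on every output.  Defaults: T = 50
for main groups, T = 5 for subgroups.  Separation is measured on raw
pairwise Hamming distances, not on network path lengths, because network
paths depend on median-vector choices.

Deterministic ordering rules (the published convention fixes only the
thresholds and the "A1 = closest to the other major haplogroup" anchor;
the rest is this package's choice):

* main groups are numbered by descending total specimen count, ties by
  lexicographically smallest member sequence;
* subgroup A of a main group contains the haplotype with the smallest
  distance to any haplotype outside the group; remaining letters follow
  by ascending such distance;
* within a subgroup, index 1 is the haplotype closest to the nearest
  other main group, then ascending by that distance (ties: descending
  member count, then sequence).

With a single main group there is no external anchor; subgroups then
order by descending specimen count and haplotypes by descending member
count, same tie-breaks.  More than 26 subgroups in one main group is a
hard error (the letter format cannot express it).

## Substitution effects

Translation uses NCBI table 5 (invertebrate mitochondrial).  Coordinates
are 1-based within each gene's aligned CDS, so position p maps to codon
⌊(p−1)/3⌋+1, codon position ((p−1) mod 3)+1.  When annotating the
differences between two haplotypes, the codon context is read from the
first haplotype; if any base of the codon falls in a masked column or in
a trailing partial codon, the effect is reported as *undetermined* rather
than guessed.  Codons with more than one differing site are reported per
site, each against the first haplotype's codon.  Ambiguity codes
translate to `X` and never silently resolve.

## Outbreak linkage

Two origins are `linked` when they share a haplotype, `proximate` when
their closest haplotypes are within the subgroup threshold (default 5)
without sharing, and `unlinked` otherwise.  The `proximate` tier goes
beyond a binary shared/not-shared call because single-mutation
neighbours within one greenhouse complex are epidemiologically a single
introduction.  Haplotype diversity (1 − Σp²) is reported as an optional
extra alongside raw haplotype counts.

## Synthetic populations

The generator plants the exact structure the classifier assumes and is
the basis of all recovery tests.  Defaults (chosen once; they define the
study conditions):

| parameter | default | rationale |
| --- | --- | --- |
| gene plan | 13 genes, lengths summing to 10,914 nt, each divisible by 3 | full protein-coding complement of an insect mitogenome |
| GC fraction of the root | 0.26 | AT-rich insect mitogenome |
| main groups | 4 | number of deep maternal lineages in the motivating system |
| mutations root→main founder | uniform 28–60 | pairwise main separations 56–120, strictly > 50 |
| subgroups per main | uniform 2–4 | |
| mutations group→subgroup founder | uniform 6–15 | pairwise subgroup separations 12–30, strictly > 5 |
| haplotypes per subgroup | uniform 1–4; extras radiate 1–2 mutations | shallow outbreak radiation |
| specimens per haplotype | geometric, mean 3, capped at 24 | skewed sampling, ~110–130 specimens |
| origins | 5 named origins, assigned per haplotype | `shared_source_pairs` forces a shared haplotype between two origins |

Mutations are placed at globally distinct columns (infinite-sites style),
so planted mutation counts equal Hamming distances exactly and every
mutation is replayable from a ledger carrying gene, position, ref/alt and
its syn/non-syn status.  Because separations are strict by construction,
threshold clustering recovers the planted partition deterministically;
this is what the 100-replicate recovery study measures.  The `corrupt`
operation injects gaps and Ns at recorded positions to exercise the
masking policy and the *undetermined* effect path.

What the generator does **not** emulate: homoplasy, recombination,
selection, rate heterogeneity, realistic codon usage, or
sequencing/assembly error beyond point corruption.  Passing recovery
tests therefore demonstrates correctness of the algorithms under the
declared model, not robustness to violations of it.

## Problem sizes and determinism

The test suite and the acceptance script run the simulator at its default
~110–130-specimen, 10,914-nt scale (100 replicates for recovery), the
median-joining/Steiner comparison on 200 radiation draws, and the
parsimony-informative-site oracle on 200 matrices up to 10 × 50.  Every
stochastic component takes an explicit integer seed (numpy `default_rng`)
and all tie-breaks are lexicographic or count-based, so identical inputs
produce byte-identical outputs; the CLI writes input hashes and stage
timings to a manifest for provenance.
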