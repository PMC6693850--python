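# mitotrace

Tracing insect pest outbreaks with mitochondrial haplotype networks.

When an invasive pest such as the pepper weevil (*Anthonomus eugenii*)
appears in a greenhouse, the immediate questions are: was it a single
introduction, where did it plausibly come from, and is it connected to
other outbreaks?  Whole-mitogenome haplotypes answer these at a resolution
single-marker barcoding cannot.  `mitotrace` implements the analysis side
of that workflow: starting from per-gene aligned CDS FASTA files (the 13
mitochondrial protein-coding genes typical of insects) and a specimen
metadata table, it

* applies the coverage-based specimen inclusion rule
  (mean coverage ≥ 10×, 100% breadth),
* concatenates the genes, masks gap/ambiguous columns, and collapses
  specimens into haplotypes,
* builds a **median-joining network** (ε = 0) over the haplotypes —
  Kruskal-style minimum spanning network construction keeping all
  equal-weight ties, augmented with majority-consensus median vectors
  (hypothetical ancestors) whenever they shorten the network,
* assigns systematic **haplogroup labels**: single-linkage clusters
  separated by more than 50 mutations become main groups 1, 2, 3, …;
  within a main group, clusters separated by more than 5 mutations become
  subgroups A, B, C, …; haplotypes are numbered within subgroups, so a
  label reads like `1D2`,
* classifies every inter-haplotype substitution as synonymous or
  non-synonymous under the **invertebrate mitochondrial code**
  (NCBI translation table 5: AGA/AGG→Ser, ATA→Met, TGA→Trp),
* and reports per-origin haplotype diversity plus pairwise **linkage
  verdicts** between outbreak locations (`linked` when a haplotype is
  shared, `proximate` within the subgroup threshold, else `unlinked`).

A synthetic-population generator with planted haplogroup structure makes
the entire pipeline testable without any sequence downloads.

## Worked example

```python
import mitotrace as mt

config = mt.SimConfig(seed=42)            # 4 main groups, >50 apart
alignments, meta, truth = mt.simulate_population(config)
kept, excluded = mt.filter_specimens(meta)

concat = mt.concatenate(alignments, kept)
masked = mt.mask_columns(concat)
table = mt.collapse_haplotypes(masked)
dm = mt.pairwise_distances(table)
assignment = mt.classify(table, dm)       # >50 / >5 mutation thresholds
network = mt.median_joining(table)        # epsilon = 0
n_pi, _ = mt.parsimony_informative_sites(masked)

rep = mt.linkage_assessment("Netherlands", "Italy", table, dm, meta)
```

Output:

```
specimens analyzed : 111
alignment width    : 10914 nt
parsimony sites    : 364
haplotypes         : 42 (28 with >1 member)
main haplogroups   : 4
network length     : 383 mutations (5 median vectors)
NL vs IT linkage   : proximate (min distance 2)
```

The 111 specimens collapse to 42 unique haplotypes falling into the four
planted maternal lineages; the median-joining network connects them with
383 mutations in total, inserting 5 hypothetical ancestors.  The linkage
verdict `proximate` means the closest Dutch and Italian haplotypes differ
by only 2 mutations without being identical — in this simulated draw both
origins sampled the same shallow radiation.

The same pipeline is available from the shell:

```bash
mitotrace simulate --seed 42 --out sim/
mitotrace all --genes sim/ --meta sim/metadata.tsv --out results/
```

which writes the haplotype table, distance matrix, GraphML network,
haplogroup assignments, substitution effects, per-origin report and a
provenance manifest into `results/`.

## Layout

| module | role |
| --- | --- |
| `mitotrace.seq_io` | FASTA/metadata I/O, inclusion rule, concatenation, GC content |
| `mitotrace.haplotypes` | column masking, haplotype collapsing, distances, PI sites, divergence |
| `mitotrace.mj_network` | minimum spanning network, median joining, exports |
| `mitotrace.haplogroups` | threshold clustering and systematic nomenclature |
| `mitotrace.codon_effects` | translation table 5, syn/non-syn classification |
| `mitotrace.outbreak_report` | per-origin diversity and linkage assessment |
| `mitotrace.synthetic_data` | planted-structure population simulator |
| `mitotrace.cli` | `mitotrace` command-line interface |

See `docs/methods.md` for the model, parameter defaults and numerical
choices.
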