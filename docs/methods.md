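# Methods

This note documents the models, parameter defaults, numerical choices and
limitations of plastomekit. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## The synthetic plastome generator

The generator (`synthetic_data`) emits a circular genome with the
canonical quadripartite architecture LSC + IRb + SSC + IRa, IRa being the
exact reverse complement of IRb. Defaults mirror a typical Lamiales
plastome: region lengths 82,695 / 25,539 / 17,555 / 25,539 bp (151,328 bp
total) and region GC targets of 36.2% (LSC), 32.0% (SSC) and 43.1% (IR).

Background sequence is drawn i.i.d. per region at the region's GC target;
genes overwrite background through a non-overlapping allocator (60 bp
minimum intergenic padding). Planted coding genes are valid ORFs (ATG
start, stop codon, no internal stop, length divisible by 3) whose codons
are sampled at the regional base composition, so gene content does not
pull regional GC off target. The emitted gene complement includes:

- a **ycf1-like** gene crossing the SSC/IRa border with 1,056 bp inside
  the IR, whose reverse-complement image forms a pseudogene fragment at
  the IRb/SSC border;
- an **ndhF-like** minus-strand gene overlapping that pseudogene fragment
  by 32 bp. The 32 shared bases serve two reading frames at once (ycf1
  through the IR mirror, ndhF directly), so they are sampled jointly under
  both frame constraints and the ndhF stop codon is placed inside the
  shared window;
- an **rps19-like** gene crossing LSC/IRb by 43 bp (pseudogene fragment of
  43 bp at the IRa/LSC border) and a **trnH-like** gene 9 bp from that
  border;
- intron-bearing genes: a trnK-like tRNA with a 2,522 bp intron, a
  clpP-like minus-strand gene with two introns, and an rps12-like
  trans-spliced gene whose 5' exon lies in the LSC and whose two 3' exons
  lie in the IR (both IR copies annotated; the 5' exon is shared);
- rRNA-like genes in the IR, generic CDS/tRNA filler genes, and two seed
  genes (psbA-like mid-LSC, ndhI-like mid-SSC) that the assembler uses as
  extension starting points. Mid-region seed placement keeps the two
  contigs' arm growth into the IRs roughly balanced.
- four rRNA-like genes and the junction genes scale down proportionally on
  toy-sized regions so small test genomes remain constructible.

Planted dispersed/tandem/SSR repeats are written verbatim at recorded
coordinates with deliberately mismatching flank columns, so each planted
tract is *maximal*: a detector reporting maximal hits recovers exactly the
planted span. Single bases at the IR borders are likewise chosen so the
IR pair cannot extend by chance, making the planted partition the unique
maximal inverted pair. Default planted repeats use the unit sequences of a
published curated plastome repeat table (four forward, two inverted pairs,
seven tandems); the third inverted pair of that table emerges
automatically as the IR image of the forward repeat planted across IRb and
SSC. Because two of the published forward units share a long common
suffix, cross-pairs between their loci are genuinely present in the
emitted genome — detectors will (correctly) report more raw dispersed hits
than the number of planted items.

One integer seed drives named substreams (background, genes, repeats,
SSRs, fixes) via `numpy.random.SeedSequence`, so genomes are reproducible
and the streams are independent.

### Read simulators

- **Long shotgun reads**: uniform start positions on the circle, random
  strand, lengths normal with mean 384 bp and sd 0.15 x mean truncated to
  [50, 2 x mean] (the emulated chemistry reports only a mean length; the
  truncated normal is a stand-in). The characteristic error mode is the
  homopolymer-length error: every run of three or more identical bases is
  lengthened or shortened by one base with probability
  `homopolymer_rate` (default 0.02 per run); substitutions optional.
- **Accurate short reads**: fixed length (default 50 bp),
  substitution-only errors at rate 0.002, no indels.

What the simulator does *not* emulate: quality scores, chimeric reads,
coverage biases, heteroplasmy, and near-identical (rather than exact) IR
copies. Passing the end-to-end tests therefore demonstrates correctness of
the algorithms under the stated error model, not robustness to every
artifact of real sequencing runs.

## Assembly

`assemble_plastome` is a two-seed greedy assembler:

1. Each seed is extended one read per end per round. Candidate reads come
   from a sparse k-mer index (k = 21) probed with the terminus k-mers;
   the qualifying read (edit-distance identity ≥ `min_identity` over the
   last `min(overlap, 150)` bases) with the largest overhang is appended,
   ties broken by identity then read id. The junction position inside the
   chosen read is fixed by a unique-anchor cut (below).
2. The pipeline default `min_overlap` is 150 bp, deliberately longer than
   the longest non-IR repeat tract of the emulated genome (108 bp): a
   qualifying overlap then always contains unique flanking sequence, so a
   read anchored entirely inside a repeated tract can never win a step.
   (The single-step `extend_contig` operation keeps the conventional 30 bp
   default for unit-scale use.)
3. Extension must stop before an arm runs through an entire IR — past the
   far border the continuation is a coin flip between the two flip-flop
   isomers. Two mechanisms enforce this: a contig whose two ends become
   mutual reverse complements (both ends inside the IR) to a depth of
   `ir_cap` (default 15,000 bp, roughly 60% of the IR) is frozen; and the
   two contigs are merged as soon as both junction overlaps (suffix-prefix
   overlaps of at least `merge_overlap` = 1,000 bp at ≥ 99% identity, in
   one consistent orientation) exist. The end-mirror depth is measured
   with an offset-tolerant probe because the two arms generally penetrate
   the IR to different depths. Single cross-orientation overlaps are
   mirror artifacts of the self-symmetric arms and never freeze anything.
4. The circle is stitched at the two junctions and the duplicated arc
   trimmed.

**Junction cuts.** Splice points (each extension step and both merge
junctions) are placed by backing off from the contig end to a 21-mer that
occurs exactly once in the junction window, then aligning the remaining
tail with a prefix-anchored alignment. Three safeguards address the
short-period ambiguities that dominate the residual error budget:

- an apparently unique anchor whose implied cut disagrees with the
  expected overlap by more than 8 bp is rejected (an error in one copy of
  a periodic tract can mask the anchor's twin and leave a shifted
  "unique" match);
- tied alignment ends are resolved so that the spliced junction preserves
  the local run-length skeleton (consecutive duplicate bases collapsed):
  the residual ambiguity then falls *inside* a homopolymer run, where the
  correction stage can repair it, instead of duplicating or dropping a
  flanking base;
- a cut whose 40 bp back-window grossly disagrees with the contig tail is
  re-tested at shifts of |2..6| bp and overridden only on a near-perfect
  realignment (a short-period mis-cut signature; |1| bp shifts are benign
  homopolymer ties and are left to the correction stage).

**Homopolymer correction.** Accurate reads are placed on the circle by
exact k-mer anchoring (reads matching both IR copies vote at both). Each
read votes on the length of every homopolymer run it spans with ≥ 10 bp
anchors: verbatim-matching reads confirm the contig (vectorized interval
counting); reads with ≤ 3 mismatches vote the run length they themselves
carry near disagreements (a pair of compensating indels presents as a few
mismatch columns, not a frameshift); other reads are aligned with edlib
and votes extracted through the alignment path. A run is rewritten when at
least `min_depth` = 5 observations give a ≥ 60% majority for a different
length. Runs down to length two are examined: a true run of three
shortened by a read error is otherwise invisible. A cheap second round
re-examines the neighborhoods of first-round rewrites.

**Isomer canonicalization.** Short-read data cannot distinguish the two
flip-flop isomers (no read spans an IR), so `structure.canonical_isomer`
maps a genome to the lexicographically smallest of the four strings
reachable by strand choice and SSC orientation after rotating the LSC to
position zero. Assemblies are compared to references in this canonical
form; this is the package's reading of sequence identity "up to rotation
and strand" for quadripartite circles.

## Structure

IR detection finds the maximal pair of disjoint intervals whose sequences
are exact reverse complements (k-mer anchoring at k = 25 on the doubled
sequence, diagonal grouping, maximal exact extension; ties to the leftmost
start). Exactness is a deliberate restriction — the emulated genomes
satisfy it — and near-identical IRs are out of scope. The canonical
linearization starts the LSC at position zero with order LSC, IRb, SSC,
IRa (IRb is the copy downstream of LSC); the input strand is preserved, so
partitioning is idempotent. Composition percentages round half-up to one
decimal, N residues are excluded from denominators.

Junction metrics: the pseudogene length of a border-spanning gene is the
number of its bases on the IR side of the junction; the ycf1-pseudogene /
ndhF overlap is the intersection of the pseudogene's mirrored interval
with the ndhF envelope; the trnH offset is the circular distance from the
IRa/LSC border to the nearest trnH base. Genes absent from the annotation
yield None, never zero.

## Gene statistics

Codon counting uses literal codons of all non-pseudo CDS features,
including stops; start-codon leniency of the organellar code is ignored
(alternative starts count as their literal codon). IR-duplicated gene
copies count once per genomic copy. RSCU treats the three stop codons as
one synonymous family — this choice reproduces published stop-codon RSCU
arithmetic (46/22/18 -> 1.60/0.77/0.63). Codon usage is computed from CDS
only: a tRNA contribution would be incoherent for RSCU, and published
totals are consistent with CDS-only counting. Intron lengths are gaps
between consecutive coding exons measured on the genome irrespective of
strand; a trans-spliced gap (negative or above 10 kb) is reported as
not-applicable. Coding fractions count each base once with precedence
CDS > tRNA > rRNA.

## Repeats

Dispersed hits are maximal windows on a diagonal (direct) or anti-diagonal
(reverse complement) with at most 3 mismatches over ≥ 30 bp, bounded by
matching columns, with disjoint loci. Redundancy rules: hits whose loci
both nest inside a longer same-kind hit are dropped; the genome-scale IR
pair itself is dropped; and hits lying entirely within the IRs are
collapsed onto their IRb-mapped canonical image (hits with only one locus
in an IR are kept — that is how the inverted image of a forward repeat
planted across IRb and SSC surfaces as its own hit, matching curated
practice). Seeding uses exact shared k-mers: k = 7 up to 20 kb (provably
complete for 30 bp / 3 mismatches by pigeonhole, and required for exact
agreement with the brute-force oracle), k = 12 at genome scale where
completeness holds for hits containing an exact 12-mer — every hit of the
curated tables does. The quadratic oracle in `brute_force_dispersed`
shares only the hit *definition*, not the search strategy.

The tandem detector is a perfect-run period scan (defaults: period 10-60,
≥ 2 copies, ≥ 30 bp total; overlapping reports collapse to the highest
copies x length, ties to the smaller period). Imperfect tandems are out of
scope; the tracts of interest in the emulated genomes are perfect.

SSRs are perfect runs trimmed to whole units at MISA-style thresholds,
reported once at their minimal period, as observed on the forward strand
(no canonical-motif collapsing), with both IR copies counted — choices
made for comparability with published census tables. An independent
regex-based oracle backs the implementation in the tests.

## Divergence

`align_pair` is a Gotoh affine-gap global aligner (match +1, mismatch -1,
gap open -5, gap extend -1, deterministic traceback preferring diagonal
over vertical over horizontal), validated against an exhaustive
memoized-recursion oracle on short strings; it exists for pairwise and toy
use — multi-gene, many-taxon alignments are consumed, not recomputed. K2P
uses pairwise deletion (maximizes usable sites; the common convention) and
flags saturation (1 - 2P - Q ≤ 0 or 1 - 2Q ≤ 0) instead of raising or
clamping; saturated pairs are excluded from per-gene means with a count.
Per-gene divergence is the unweighted mean over unordered taxon pairs.
The known-truth generator evolves star-tree gene families under
Jukes-Cantor with per-gene rates, so the expected pairwise distance of a
gene equals its rate; rank-recovery tests run three rate classes (0.02 /
0.08 / 0.20 substitutions per site) at 900 sites and 4 taxa.

## Phylogenetics

Fitch scoring treats characters as unordered and gaps/ambiguities as
missing data (full state set). CI includes parsimony-uninformative sites
by default (the convention of the classic implementations), with switches
for informative-only scoring and for excluding gapped columns. CI is
undefined (None) for constant data and RI is undefined when maximum and
minimum steps coincide. Neighbor joining follows Saitou-Nei with
deterministic tie-breaking by cluster label and negative branch lengths
clamped to zero; it is exact on additive matrices and cross-checked
against an independent implementation in the tests. The parsimony search
uses random-addition starts with NNI hill climbing — a desk-scale stand-in
for TBR heuristics — and is validated against exhaustive enumeration of
all topologies for small taxon sets. Bootstrap support resamples columns
with replacement and reports the percentage of replicates containing each
bipartition of the point-estimate tree.

## Problem sizes used in the shipped checks

The test suite and acceptance script validate the assembler end-to-end at
the full default genome size (151,328 bp, 60x shotgun + 60x accurate
coverage) across 20 seeds in the suite and 8 seeds in the acceptance
script; oracle comparisons run at 1.5-3 kb (dispersed repeats), 8-10 kb
(SSRs), up to 12 bp (alignment) and 6-7 taxa (trees), the scales at which
exhaustive computation is sensible. These sizes are the package's choice
of thorough-but-quick validation scales.

## Known limitations

- IR copies must be exact reverse complements for structure detection.
- The assembler targets the quadripartite architecture; genomes with
  large rearrangements, or IRs shorter than about twice `merge_overlap`,
  are out of scope (`ir_cap` must be set below the IR length).
- Tandem detection is perfect-copy only; compound/imperfect SSRs are not
  reported.
- The polymorphism scan is substitution-level (indel polymorphisms are
  not called).
- Bootstrap and search budgets are desk-scale; no attempt is made to
  reproduce searches over dozens of full genomes.
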