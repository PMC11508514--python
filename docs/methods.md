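# Methods

This note documents the models and procedures implemented in `mitoscolia`,
the conventions chosen where several were defensible, and what the synthetic
data can and cannot establish.

## Composition statistics

Base counts are exact tallies over {A, C, G, T}; IUPAC ambiguity codes are
tallied as N and excluded from every denominator, so A+T content is
(A+T)/(A+C+G+T). Skews are AT-skew = (A − T)/(A + T) and
GC-skew = (G − C)/(G + C), computed on the majority strand — the strand the
record stores, which in insect mitogenomes carries most protein-coding
genes. Reversing the strand negates both skews (a tested invariant). A
whole-record mode (including the control region) and a PCG-only mode are
both provided, since studies report the two side by side; percentages are
conventionally read at one decimal.

Codon usage pools all 13 protein-coding genes of a genome. Each CDS is read
5′→3′ on its own strand from the annotated start. Terminal stop codons are
excluded, including the incomplete stops (a trailing `T` or `TA` completed
by polyadenylation) that mitochondrial annotations commonly carry; any other
trailing partial codon is dropped with a warning, and internal stops are
recorded as warnings rather than errors, because they usually indicate an
annotation slip, not corrupt data. RSCU uses the synonymous families of the
invertebrate mitochondrial code (table 5, configurable), under which Ser has
an eight-codon family (UCN + AGN) and AUA codes Met; families with zero
total are reported as missing, not zero, to keep them out of averages.
Multi-genome codon frequencies are reported pooled over genomes by default
(per-genome averaging is available via the per-genome columns); pooling was
chosen because family-level summaries of codon use conventionally weight by
codon count, but nothing downstream depends on the choice.

Group summaries (per-tribe A+T means) are arithmetic means over member
genomes; this is an interpretive choice where a source table might have used
another weighting.

## Gene orders and rearrangement classification

A gene order is a circular signed permutation over the 37 canonical genes,
with duplicates carried as (label, copy) pairs — most scoliid genomes have
an extra trnM — and the control region excluded (it is absent from short
assemblies). Extraction sorts features by start coordinate, normalises the
reading direction so the majority of PCGs are on +, and cuts the circle at
trnI (falling back to cox1, then the first gene). The anchor never creates
artificial breakpoints: comparisons treat both orders as circular.

Classification against the ancestral insect arrangement finds a
maximum-length common signed subsequence (the *anchor set*) between the two
circular orders; the reference linearisation is fixed and all rotations of
the query are scanned, which covers every circular alignment. Ties between
equal-length anchor sets prefer the set containing more PCGs, then resolve
deterministically by traversal order. Anchored genes are *conserved*; the
rest are classified per gene: sign flipped with unchanged neighbours →
*inversion*; moved with flipped sign → *inverse transposition*; moved with
the same sign → *transposition*, sub-labelled *shuffled* when the gene stays
between the same flanking PCG/rRNA genes (the behaviour of tRNA clusters
such as trnI–trnK). This is deliberately descriptive — a per-gene event
table, not a minimum-event rearrangement scenario; scenario inference
(DCJ/HP distances, tandem-duplication models) is out of scope. On 1,000
random single edits of the ancestral order the classifier reports the
applied event for the edited gene ~98% of the time; the residue are edits
that are genuinely ambiguous (e.g. a move of one slot equals a move of the
neighbour the other way, and a flip that lands between its old neighbours is
indistinguishable from an in-place inversion).

The breakpoint distance counts circular signed adjacencies of one order
absent from the other (orientation-aware, reading-direction-free); a single
interior segment reversal yields exactly 2.

### Cluster modes

The tribe-diagnostic blocks are scored from signed patterns held as data,
not code: cluster 1, mode 1 `[+trnL2, −trnM]` / mode 2 `[+trnM, −trnL2]`;
cluster 2, mode 3 `[+trnH, +nad5, −trnE]` / mode 4 `[+trnE, −nad5, −trnH]`
(`(−X)` in the hyphenated display notation means X inverted). Within each
cluster the two modes are exact reverse complements of one another — they
are the same double-stranded block read from opposite sides — so they are
only distinguishable in a fixed genomic frame. Detection therefore
orientation-normalises the order (PCG-majority strand = +) and then matches
patterns as contiguous circular runs in the forward reading only. This
makes detection invariant under reverse-complementing the whole genome
while keeping the modes distinct; matching pattern reverse complements
directly would collapse mode 1 with mode 2 and mode 3 with mode 4. Any copy
of a duplicated label may participate in a match; a cluster whose genes are
absent, or that matches no pattern (or, pathologically, more than one),
degrades to `unknown` — the missing-data state that the short
*Campsomeriella* and *Liacos* assemblies receive.

## Ancestral-state reconstruction

The two cluster characters are treated as independent binary characters
(matching their separate panels in tribe-level analyses), with `?` meaning
full uncertainty: a likelihood of 1 in every state, the full state set
under parsimony.

**Parsimony.** The Fitch dynamic program, generalised to polytomies by
Hartigan's count rule (so a trifurcating root is handled exactly), returns
per-node state sets and the minimal change count; agreement with exhaustive
enumeration over internal labelings is tested on thousands of random
five-tip characters.

**Likelihood.** Mk1 has one symmetric rate q per unit branch length with
the closed form P_ii(t) = 1/k + (k−1)/k·e^{−kqt}; AsymmMk (two states) has
rates (q01, q10) with the standard two-state closed form. Root priors are
uniform for Mk1 and the stationary distribution (q10, q01)/(q01 + q10) for
AsymmMk — the conventional choices where a source analysis is silent. The
pruning algorithm runs over a post-order index of the (dendropy) tree with
per-node rescaling, vectorised across characters so that joint fits of
hundreds of characters cost little more than one. Rates are fitted on the
log scale within [1e−8, 1e3] by bounded scalar search (Mk1, three
subintervals) or L-BFGS-B from three starts (AsymmMk, seeded for
reproducibility); fits at the bounds — e.g. for monomorphic characters —
are flagged rather than hidden. Models are compared by AIC = 2k − 2 lnL
with ties going to fewer parameters. Marginal posteriors at internal nodes
come from the standard inside/outside pass, which is exact for the
non-reversible AsymmMk as well; all reconstructions are keyed by a node's
tip-set signature so they survive serialisation. Under Mk1 the likelihood
is invariant to child order and to re-rooting along a branch (tested);
zero-length trees with conflicting tips give lnL = −∞, not an exception.

Joint (max-posterior-path) reconstruction and stochastic character mapping
are not implemented.

### The Scoliidae fixture

The packaged 15-taxon topology is transcribed from the study's prose
description of its mitogenome tree (tribe split; *Colpa* sister to the
Scoliini; *Megacampsomeris* + *Sericocampsomeris*, then *Micromeriella*,
*Phalerimeris* and *Campsomeriella* successively basal within Campsomerini;
*Scolia* + *Austroscolia* sister to *Megascolia* + (*Liacos* +
*Carinoscolia*)). Three nodes the prose leaves unresolved — within
*Megacampsomeris*, within *Scolia* + *Austroscolia*, and *Micromeriella*'s
exact attachment — were fixed once to an arbitrary binary resolution;
none of them affects the tribe-level reconstructions. The original branch
lengths were not published, so the fixture defaults to unit branch lengths
and flags them as defaulted; consequently the node probabilities computed
here characterise the topology + unit-lengths condition, not the original
analysis, and only qualitative statements (majority state at a node)
transfer. Under that condition the Mk1 marginals at the family root are
0.662 for mode 1 and 0.662 for mode 3 — the Scoliini-type arrangement is
the majority reconstruction for both clusters, and the crown of the scored
Campsomerini reconstructs the derived modes 2/4 essentially certainly.
Parsimony, by contrast, places the root exactly one change from either
resolution (the Campsomerini subtree resolves cleanly to mode 2/4, the
*Colpa* + Scoliini subtree to mode 1/3), so the Fitch root set is
genuinely equivocal, {mode1, mode2} and {mode3, mode4}; a singleton MP
root is not obtainable from these tip data on this topology.

## Synthetic data

The simulator emulates: circular ~15–17 kb genomes with realistic per-gene
lengths, valid start (ATG) and stop (TAA) codons under the invertebrate
code, codon-sampled PCG bodies with internal stops excluded (so RSCU has
non-trivial structure), short random intergenic spacers, a control region
filling the genome to the target length, the duplicated trnM, and gene
orders built from the ancestral arrangement by explicit edits or by the
`order_with_modes` archetypes. The per-base A+T probability of PCG bodies
is solved (Brent's method) so that the stop-conditioned codon distribution
hits the target A+T; realised whole-genome A+T matches the target within
~0.01 in expectation. The default target (0.82) sits mid-range of the
0.75–0.87 observed across scoliid genomes. Trees are uniform over labelled
histories with i.i.d. exponential branch lengths (mean 0.3); characters
evolve by drawing states down the tree from the model's transition
matrices. One integer seed drives a `SeedSequence` hierarchy, so outputs
are byte-identical per seed.

What the simulator does **not** emulate: annotation error, sequencing or
assembly artefacts, boundary uncertainty between genes, rate variation
along the genome, and base composition heterogeneity among genes. Passing
round-trip tests on synthetic data therefore demonstrates internal
consistency of extraction → classification → reconstruction, not
robustness to noisy real annotations; the normalisation layer
(`normalize_gene_name`, strand/orientation handling) is exercised
separately on dialect examples.

## Problem sizes used in the checks

The acceptance checks run the enumeration oracles on 100 random trees of
2–6 tips and 500 five-tip parsimony characters; rate recovery fits 1,000
single characters (q = 0.5, 100-tip tree) and model selection runs 100
replicates of joint 500-character fits under q01 = 5·q10; the gene-order
round trip draws 1,000 seeded single edits. These sizes give stable medians
and rates (Monte-Carlo error well inside the asserted bands) while keeping
a full run in minutes on one core.

## Known limitations

* Event classification is per-gene and descriptive; complex multi-gene
  events are reported as their per-gene footprints.
* The mode patterns encode one display convention for the cluster blocks;
  a study using the opposite frame convention can swap the pattern table
  (`CLUSTER_PATTERNS`) without code changes.
* AsymmMk's root prior is fixed at the stationary distribution; an
  estimated or flat alternative would change node probabilities somewhat.
* GenBank reading covers CDS/tRNA/rRNA/D-loop features with common
  name dialects; exotic dialects fall through as `kind=other` (kept, and
  warned about during order extraction rather than silently dropped).
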