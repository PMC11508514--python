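# mitoscolia

Comparative mitogenomics of scoliid wasps (Hymenoptera: Scoliidae) — and of
circular animal mitogenomes generally. The package is aimed at researchers who
have annotated mitochondrial genomes and a phylogeny and want, in one tested
toolchain, the three analyses that comparative mitogenome papers chain
together:

1. **Nucleotide composition** — per-genome base counts, A+T content, strand
   asymmetry as AT-skew = (A − T)/(A + T) and GC-skew = (G − C)/(G + C)
   computed on the majority strand, and relative synonymous codon usage

   RSCU(c) = n_c · |F(c)| / Σ_{c′∈F(c)} n_{c′}

   where F(c) is the synonymous family of codon c under the invertebrate
   mitochondrial code (NCBI table 5).

2. **Gene-order rearrangement** — signed, duplicate-aware gene orders
   extracted from annotations, compared against the ancestral insect
   (*Drosophila*-type) arrangement via a maximum-length common signed
   subsequence; the remaining genes are classified as inversions,
   transpositions (with a *shuffled* sub-type for intra-interval tRNA moves)
   or inverse transpositions, plus a circular signed breakpoint distance.
   Two diagnostic blocks are scored as binary characters: the trnL2/trnM
   block (*cluster 1*: mode 1 `trnL2-(-trnM)` vs mode 2 `trnM-(-trnL2)`) and
   the trnH/nad5/trnE block (*cluster 2*: mode 3 `trnH-nad5-(-trnE)` vs mode
   4 `trnE-(-nad5)-(-trnH)`), the arrangements that separate the tribes
   Scoliini and Campsomerini.

3. **Ancestral-state reconstruction** of those cluster modes on a rooted
   tree: Fitch/Hartigan maximum parsimony, and maximum likelihood under the
   Mk1 (one symmetric rate q) or AsymmMk (two rates q01, q10) models with
   transition probabilities P(t) = e^{Qt}, Felsenstein pruning, AIC model
   choice (AIC = 2k − 2 lnL) and marginal posterior state probabilities at
   every node. Missing data are carried as full uncertainty, never dropped.

A synthetic-data module simulates annotated mitogenomes with controlled A+T
content and gene order, random trees, and characters evolved under Mk models,
so the entire pipeline is testable without downloads.

## Worked example

```python
import mitoscolia as m
from mitoscolia.data import scoliidae_tree, scoliidae_modes, scoliidae_root_signature

# simulate an annotated mitogenome with the Scoliini-type arrangement
g = m.simulate_mitogenome(m.SimulationConfig(seed=1, target_at=0.80,
                                             gene_order="scoliini_like"))
order = m.extract_gene_order(g)
print(m.detect_cluster_modes(order))      # -> ('mode1', 'mode3')

# ancestral states of the cluster modes on the packaged Scoliidae topology
tree, matrix = scoliidae_tree(), scoliidae_modes()
states = matrix.column("cluster1")
fit = m.fit_model(tree, states, "Mk1", alphabet=("mode1", "mode2"))
print(fit.summary())
rec = m.marginal_reconstruction(tree, states, fit)
print(rec.ml_at(scoliidae_root_signature()))
```

This prints the fitted model

```
Mk1 model, 2 states ('mode1', 'mode2')
  rates:      0.0415514
  lnL:        -3.8021
  n_params:   1
  AIC:        9.6043
  root prior: 0.5000, 0.5000
```

and the family-root marginals `{'mode1': 0.6616, 'mode2': 0.3384}`: under
unit branch lengths, the Scoliini-type arrangement of cluster 1 (mode 1) is
the majority reconstruction at the root of Scoliidae — the same holds for
mode 3 of cluster 2 — mirroring the finding that *Colpa tartara*, though
traditionally placed near Campsomerini, shares the Scoliini-type ancestral
arrangement.

The same analyses are available from a shell:

```bash
mitoscolia simulate --seed 3 --n-taxa 12 --out-dir study/
mitoscolia run --config config.yaml     # features -> rscu -> order -> modes -> asr
```

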