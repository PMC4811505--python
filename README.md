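# ripscan

Identification and characterization of the mRNA targets of an RNA-binding
protein from RIP-Seq data (RNA immunoprecipitation followed by sequencing),
built around the analysis design used for the p53-induced ARE-binding
protein Wig-1/Zmat3: triplicate IP and input libraries from cells expressing
the tagged protein (W), an empty-vector control (C) and, optionally, an
RNA-binding-deficient mutant (Wmut).

The package is aimed at computational biologists who have gene-level read
counts from such an experiment (or want to prototype the analysis on
synthetic data with known ground truth) and need the full downstream chain:

* **Enrichment calling** — counts are transformed to log2-CPM with
  observation-level precision weights from a fitted mean–variance trend
  (voom-style), and each gene is tested with an empirical-Bayes moderated
  t-statistic on the double-difference contrast

  ```
  log2FC = (IP.W − IP.C) − (input.W − input.C)
  ```

  which isolates pulldown enrichment specific to the tagged protein from
  background binding and expression differences. A transcript is called
  bound when log2FC > 1 (more than 2-fold enrichment) and the
  Benjamini–Hochberg adjusted p-value is below 0.05; a dual criterion
  additionally requires enrichment over the binding-dead mutant, and bound
  sets from different cell lines can be intersected.
* **Regulation integration** — bound transcripts are crossed with
  knockdown/control expression; a gene is regulated when its
  knockdown/control ratio differs more than 4-fold in at least 2 of 3
  replicate pairs, giving the up/down split that distinguishes a
  stabilizing from a destabilizing RNA-binding protein.
* **ARE sequence statistics** — 3′UTRs are scanned for AU-rich elements:
  overlapping AUUUA pentamers, consecutive pentamers (AUUUAUUUA), polyU
  stretches (≥ 17 nt) and GC content, with the classical class I/II/III
  assignment. Group prevalences (bound vs shuffled or unbound controls) are
  compared with the two-sided two-proportion chi-square test with
  continuity correction, and a discriminative k-mer search (exact words up
  to 8 nt, one-sided Fisher exact test, Bonferroni-style E-values) recovers
  enriched motifs de novo.
* **Network enrichment (NEA)** — connectivity between the bound set and
  pathway gene sets in a global interaction network is scored as the number
  of crossing edges against the degree-product null expectation
  Σ d_i d_j / 2E, with an analytic z/p and a degree-preserving rewiring
  permutation mode, BH-adjusted across pathways.
* **Secondary-structure consensus** — candidate binding regions are folded
  by the Nussinov maximum-base-pairing dynamic program (Watson–Crick + G·U
  wobble, hairpin loops ≥ 3 nt), aligned by center-star progressive
  alignment, summarized as a majority consensus with a dot-bracket
  structure and GC fraction, and located relative to AREs on the primary
  sequence.
* **Synthetic data** — negative-binomial count matrices with planted
  IP-specific enrichment, AU-rich UTRs with planted pentamers and
  U-stretches, over-wired interaction networks and concordant knockdown
  expression, all with truth tables, so every stage can be validated
  against known ground truth.

## Worked example

```python
import ripscan as rs

cfg = rs.RipSimConfig(n_genes=1000, n_enriched=50, enrichment_log2fc=2.0,
                      dispersion=0.05, seed=1)
counts, truth = rs.simulate_ripseq_counts(cfg)
res = rs.fit_contrast(rs.normalize_counts(counts))
bound = rs.call_enriched(res, name="bound")
```

Running `python examples/01_enrichment_calling.py` (the same computation)
prints:

```
called 50 of 1000 genes bound
recall of planted genes: 0.98  (fraction of the 50 recovered)
false discovery proportion: 0.020
mean log2FC estimate over planted genes: 2.03 (truth 2.0)
```

49 of the 50 transcripts planted with 4-fold IP-specific enrichment are
recovered, one background gene slips in (realized FDR 2%, under the nominal
5%), and the contrast estimate is unbiased for the planted log2 fold change
of 2. The other scripts in `examples/` demonstrate regulation integration,
ARE scanning, network enrichment, consensus folding and the end-to-end
pipeline; the `ripscan` command exposes the same stages from the shell
(`ripscan simulate | enrich | integrate | motif | nea | fold | consensus |
run`).

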