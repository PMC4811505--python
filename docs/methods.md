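# Methods

## Enrichment model

Gene-level counts from triplicate IP and input libraries (conditions C =
empty vector, W = tagged protein, optionally Wmut = binding-dead mutant)
are transformed to

    y_gj = log2( (k_gj + c) / (N_j + 2c) * 1e6 ),    c = 0.5,

where k_gj is the count of gene g in sample j and N_j the library size
(column sum unless supplied). The pseudocount keeps zero counts finite and
the 2c in the denominator keeps the transform scale-invariant: multiplying
a column and its library size by the same constant leaves y unchanged.

Precision weights follow the voom idea. A cell-means model over the
(condition, fraction) groups is fitted per gene; the square root of each
gene's residual standard deviation is regressed on its mean log2 count by
lowess (span 0.5), and the trend is linearly interpolated at every
observation's fitted log2 count (clamped to the trend's end values outside
its range). The weight is the interpolated quarter-root variance raised to
the −4, i.e. the reciprocal of the predicted variance of y at that
abundance. Genes with zero counts in every sample are dropped before
fitting (count logged). When the residual standard deviation is constant
across genes — which happens in degenerate noiseless toys — the trend is
flat by construction and the lowess step is skipped.

Per gene, weighted least squares on the cell-means design reduces to
weighted group means; the contrast

    log2FC = (IP.W − IP.C) − (input.W − input.C)

(and its Wmut analogue) has unscaled variance Σ_k c_k² / S_k with S_k the
summed weights of group k. Residual variances are shrunk toward a common
prior by empirical Bayes: a scaled inverse-chi-square prior is fitted by
method of moments on the log variances (the excess variance of
log s² over the trigamma term gives the prior degrees of freedom via a
Newton inversion of the trigamma function; the mean gives the prior
variance), and the posterior variance is the df-weighted combination. The
moderated t uses residual + prior degrees of freedom and a two-sided p.
Calling applies strict thresholds, log2FC > 1 and BH-adjusted p < 0.05,
as a post-hoc filter (no fold-change-aware test). The dual criterion is
the intersection of the two single-contrast calls fitted on the same
normalized matrix. BH adjustment is the standard step-up procedure
(delegated to statsmodels).

The lowess span (0.5), the pseudocount (0.5) and the strict-inequality
thresholds are the conventional defaults of this model family; none of
them is tuned.

## Regulation rule

Knockdown/control ratios are formed per paired replicate on the linear
scale. A gene is upregulated when strictly more than `threshold` (default
4)-fold in at least `min_reps` (default 2) of 3 pairs, downregulated when
below 1/threshold symmetrically; the pathological both-directions case is
called none with a warning. Percentages in the bound-and-regulated summary
are rounded to the nearest integer of 100·count/total.

## ARE statistics

Sequences are canonicalized to RNA (T→U, uppercase); anything outside
{A,C,G,U} is rejected with its position unless N is explicitly admitted
(N counts in the GC denominator and never matches a motif). Pentamer
occurrences are counted with overlap, so AUUUAUUUA counts 2. Class
assignment precedence is II (consecutive pentamers) > I (any pentamer;
counts above 3 remain class I — the classical "1–3 scattered" is read as
typical, not exclusive) > III (U-run ≥ 17 nt without a pentamer) > none.
The U-stretch threshold is inclusive (exactly 17 U's qualifies).

The two-group prevalence test is the textbook two-sample proportion
chi-square with Yates continuity correction (the formulation behind R's
`prop.test`), written out directly because statsmodels exposes no
continuity-corrected two-sample version; the tests validate it against an
exact label-permutation oracle. The shuffled control is a uniform
mononucleotide permutation (composition and length preserved exactly); the
unbound control is a uniform sample from expressed-minus-bound genes.

The discriminative k-mer search is a deliberate simplification of
heuristic motif discovery: only exact-letter words of length 3–8, counted
by sequence containment, scored by the one-sided hypergeometric tail
(Fisher exact) for enrichment in the positive set, with a Bonferroni-style
E-value = p × (number of distinct words evaluated across all k). No IUPAC
wildcards and no greedy refinement; the aim is recovery of planted exact
motifs, not full generality.

## Network enrichment

Connectivity between a query set (AGS) and a pathway (FGS) is the number
of network edges with one endpoint in each set, edges inside the overlap
counted once. The null expectation conditions on degrees:

    E = Σ_{i∈AGS} Σ_{j∈FGS, j≠i} d_i d_j / (2|E|),

unordered pairs counted once to match the observed convention, genes
absent from the network contributing zero degree. The score is
z = (obs − E)/√E with a one-sided upper-tail normal p — a Poisson-like
approximation appropriate when E is small relative to the edge count. The
exact null of the published NEA methodology is not reproduced here; the
analytic form is validated against the degree-preserving rewiring
(double-edge-swap) permutation mode, which can also replace the analytic p
directly (empirical tail with the +1 correction). Edge confidences are
used only for the ≥-cutoff filter (default 0.5), never as weights.

## Structure and consensus

Folding is the Nussinov maximum-base-pairing dynamic program over nested
structures with A-U, G-C and G-U pairs and hairpin loops of at least
`min_loop` = 3 unpaired nucleotides (steric minimum). Tie-breaking is
deterministic: leaving the left end unpaired wins ties, otherwise the
smallest admissible partner. This is a desk-scale substitute for
thermodynamic folding: claims about structures are scoped to
maximum-pairing topology (e.g. "folds into a hairpin"), not free energies.

Regions (≤ 100 nt) are aligned by center-star progressive alignment under
match +2 / mismatch −1 / gap −2 scoring with deterministic traceback; the
center is the member with the highest summed pairwise score (ties by
lexicographic id), and previously placed gaps are never revised. The
consensus takes the per-column majority base (gap-majority columns
dropped, base ties resolved alphabetically), and its GC and fold are
computed on the gap-stripped string. This replaces simultaneous
fold-and-align (Sankoff-style) methods; with near-identical input regions
— the regime the consensus-motif analysis operates in — the center-star
consensus coincides with theirs.

Motif-to-ARE distance uses 0-based half-open spans; the distance is the
number of nucleotides strictly between the motif span and the nearest
AUUUA span (0 when they touch or overlap), with a strict <165 nt proximity
flag. A UTR without any pentamer yields an undefined (None) distance.

## Synthetic data

The count generator draws per-gene baseline abundances uniformly in
log2 CPM (default 0–9), a per-gene IP-efficiency shift shared across
conditions (normal, sd 0.5 log2 — background pulldown), and injects the
enrichment effect multiplicatively into IP.W only, so the
double-difference contrast is the estimand by construction. Counts are
negative binomial with variance μ + φμ² and a single shared dispersion
(default φ = 0.05, a typical bulk replicate-level value); at φ = 0 counts
are the rounded means, making zero-effect configurations exactly null.
Library sizes default to 15 million ± 15% (uniform), matching the
sequencing depth scale of the triplicate RIP libraries the design
emulates. Truth tables assign enriched genes an up/down regulation
direction with the 88/12 split reported for bound-and-regulated
transcripts, which the knockdown generator then realizes as planted fold
changes with multiplicative log-normal noise.

UTR backbones are built at the exact target composition (counts of
G/C/A/U fixed by rounding, then shuffled) — so realized GC is within
rounding of the target — with planted features overwriting the backbone at
non-overlapping positions: AUUUA pentamers at a per-kb rate, a 17-nt polyU
run with a configured probability, and an optional fixed region in a
stated subset. A prevalence mode plants ≥1 pentamer in an exact fraction
of sequences and destroys chance pentamers (middle-base flip), for designs
that control feature prevalence rather than rate. Defaults mirror the
bound-group statistics the analysis targets: 286 sequences, 425–1994 nt,
33% GC.

The network generator draws a uniform G(n, m) graph (exact edge count;
degree structure is conditioned on by the NEA statistic, so a scale-free
degree law adds nothing at desk scale) and, for planted designs, adds
approximately `planted_connectivity` × the random expectation of extra
AGS–pathway crossing edges.

What the generators do not emulate: read-level artifacts (duplicates,
mapping bias), gene length effects, correlated dispersions, annotation
ambiguity, and real pathway/network topology. Passing tests therefore
demonstrate the correctness and calibration of the statistical machinery
under its own assumptions, not performance on any particular real dataset.

## Problem sizes and determinism

The standard validation runs use 1000 genes with 50 planted enrichments
(recovery), 2000 genes (null calibration), 286 UTRs per group (prevalence
contrast), 500-node/5000-edge networks with 50 decoy pathways, and
folding oracles exhaustive up to length 12 — sizes at which every
ground-truth property is measurable in seconds. Every generator and the
whole pipeline are deterministic under a fixed seed (one global seed
spawns independent child streams); the end-to-end report is byte-identical
across reruns.

## Known limitations

- The moderated fit assumes a common mean–variance trend and shared
  residual structure; single-cell-scale zero inflation is out of scope.
- The analytic NEA p is an approximation; for small expected counts or
  heavy-tailed degree sequences the permutation mode is the reference.
- Nussinov folding maximizes pair count, which can differ qualitatively
  from minimum-free-energy structures for longer sequences; conclusions
  are restricted to short motifs.
- The k-mer search cannot represent degenerate motifs; a planted motif
  with variable positions is recovered only through its conserved core.
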