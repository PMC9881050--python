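# Methods

`targetrank` predicts which human proteins are plausible therapeutic
targets of protein and peptide drugs. Known targets of approved drugs
differ from other proteins across many measurable properties —
secretion and membrane signals, signaling-pathway membership, network
centrality, tissue-specific expression, transcriptional regulation —
and the package turns those differences into a genome-wide ranking
score.

## The model

For a feature `f` with gold-standard positive (target) and negative
(non-target) sets of sizes `T` and `F`, the evidence weight is the
likelihood ratio

    LR(f) = P(f | target) / P(f | non-target) = (TP_f / T) / (FP_f / F)

where `TP_f` and `FP_f` count gold-standard proteins falling in the
feature's bin. Under the naive independence assumption the combined
score of a protein with feature values `f1 ... fn` is the product

    LR(f1...fn) = prod_i LR(fi)

which is proportional to the posterior odds of being a target (the
prior odds are a genome-wide constant) and is used directly as the
prediction score. Binary features use their two categories as bins;
continuous features are cut into `n_bins = 5` equal-frequency bins
computed on the pooled labeled training values. A pseudocount
`alpha = 0.5` per bin keeps every LR finite when a bin is empty in one
class (`alpha = 0` reproduces the raw ratio exactly); the smoothed form
is `((TP_f + a)/(T + k a)) / ((FP_f + a)/(F + k a))` over `k` bins.
Scores are accumulated in log space and reported in linear space. A
missing feature value contributes a neutral factor of 1, which keeps
the product defined genome-wide without imputing values.

Ranked outputs carry confidence grades with configurable cutoffs
(default: combined LR >= 100 high, >= 1 median, else low — the score
scale is data-dependent, so these are presentation defaults, not
calibrated probabilities).

## Features

- **Sequence physicochemistry** (from FASTA): percentages of the nine
  overlapping amino-acid classes (tiny, small, aliphatic, aromatic,
  nonpolar, polar, charged, basic, acidic — B and Z count in the
  classes of their resolved residues); GRAVY (mean Kyte–Doolittle
  hydropathy); net charge under the pepstats convention (K,R = +1,
  H = +0.5, D,E = −1, B,Z = −0.5, termini ignored); theoretical pI
  (Henderson–Hasselbalch net charge with the Bjellqvist pKa set,
  termini included, root found by bisection on [0, 14] to |charge| <
  1e−3); the number of "potential" PEST proteolytic motifs; and the
  FoldIndex disorder score.
- **PEST motifs**: candidate regions are maximal stretches free of
  K/R/H, bounded by such residues or the termini, at least 10 residues
  long (sequences shorter than the window plus two flanks yield none),
  containing at least one P, one of D/E and one of S/T. The score is
  `0.55 * DEPST − 0.5 * HI` with DEPST the mass percent of D/E/P/S/T
  residues and HI the mean Kyte–Doolittle hydropathy rescaled to
  [0, 90]; a score >= 5 makes the motif "potential". All constants sit
  in one table (`PEST_CONSTANTS`, `RESIDUE_MASS`) so they can be
  recalibrated against an external epestfind run.
- **FoldIndex disorder**: per-position index
  `2.785 <H> − |<R>| − 1.151` over a centered window of 51 residues
  (truncated at the termini), with `<H>` the mean scaled hydropathy
  `(KD + 4.5)/9` and `<R>` the mean unit residue charge (K,R = +1,
  D,E = −1, H neutral, as in the original FoldIndex definition).
  Maximal negative-index runs of length >= 30 count as disordered; the
  score is their summed length over the sequence length.
- **Expression**: the tissue specificity score
  `TSPS = sum_i f_i log2(f_i / p)` with `f_i` the expression fraction
  in tissue `i` and `p = 1/n` — the KL divergence (bits) of the
  expression profile from uniform; and the housekeeping flag (detected
  in every tissue; "detected" means strictly above a configurable
  threshold, default 0, since public expression matrices do not agree
  on a detection cutoff).
- **Polymorphism**: `C_ratio = (N_ns + 0.01) / (N_s + 0.01)`, the
  smoothed ratio of nonsynonymous to synonymous SNP counts.
- **Networks**: degree (distinct partners; a self-loop is not a
  partner but sets the self-interaction flag) and normalized
  betweenness `B(n) = 2 sum_{s≠n≠t} [σ_st(n)/σ_st] / ((N−1)(N−2))`
  (unweighted shortest paths, unordered pairs, disconnected pairs
  skipped) in the undirected PPI and signal-transduction networks, and
  in/out-degree in the directed TF→target network. Whole-graph
  betweenness runs on igraph's exact C implementation; unit tests pin
  it to brute-force path enumeration. Disease relevance is the minimum
  shortest-path distance from a protein to any known disease gene
  (0 when the protein is itself one).
- **Annotation flags and counts** consumed as inputs: signal peptide,
  transmembrane region, signaling molecule, TF, enzyme, GPCR, ion
  channel, NHR, kinase, transporter, domain count, age class (1–16),
  evolutionary rate, reaction and pathway counts.

## Gold standard and evaluation protocol

Positives are the non-redundant known targets: a greedy pass in
lexicographic id order keeps a protein iff its global-alignment
identity (Needleman–Wunsch, BLOSUM62, gap open/extend 10/0.5; identity
= matches / alignment length) to every kept protein is <= 40%.
Negatives are drawn uniformly without replacement from the genome
minus all known and possible targets; because this draw is arbitrary,
it is repeated (default 100 replicate sets of 100, each from a
sub-seed of one master seed) and every reported performance number is
the mean ± SD over replicates.

Cross-validation is stratified 10-fold per replicate, the model
(bin edges and LR tables alike) refitted on each training fold, and
one AUC computed from the pooled held-out scores — pooling is used
because per-fold ROC on ~10 held-out positives is unstable.
`folds = n` falls back to leave-one-out. AUC is the Mann–Whitney
statistic (ties credited 0.5). The independent test trains one model
per gold replicate and scores it against every independent negative
replicate (an `n × n` grid of AUCs); training/test positive overlap
raises an error rather than leaking.

Feature comparisons between targets and non-targets use one-sided
Wilcoxon rank-sum tests for continuous features and one-sided Fisher
exact tests for binary ones, each in the direction of the observed
effect, with Benjamini–Hochberg adjustment across all tested features.

## mRMR feature ranking

Relevance `I(f, c)` and redundancy `I(f_i, f_j)` are plug-in mutual
information (bits) on discretized values: binary features pass
through; continuous features get 3 states at mean ± SD of the labeled
training values. Because the negative sets are replicated, every MI
term is the mean over replicates. Selection is greedy: the first
feature maximizes relevance; each later step maximizes
`I(f_j, c) / mean_{f_i in S} I(f_j, f_i)`. Conventions at the
boundaries: zero mean redundancy with positive relevance is treated as
a +infinite quotient (such candidates are ordered by relevance); a
zero-relevance candidate gets quotient 0 even when its redundancy is
also 0, because a feature carrying no class information can never
maximize the quotient — without this rule, flags absent from both
labeled sets would be selected second. Remaining ties break
lexicographically by feature name. The quotient (MIQ) form is the one
implemented; the difference (MID) variant is out of scope. Incremental
models `Model_1 ... Model_k` refit the classifier from scratch on the
top-j ranked features and are compared by replicated CV AUC.

## Synthetic genome generator

Real gold standards derive from curated drug-target databases that
cannot be redistributed, so the package ships a generator whose
defaults encode the reported effect structure of protein-drug targets:

- binary flags are Bernoulli with the published class-conditional
  prevalences (signal peptide 84.85% vs 15.24%, transmembrane 66.67%
  vs 24.60%, signaling molecule 90.91% vs 25.70%, housekeeping 24.24%
  vs 50.52%, ...);
- expression fractions are symmetric Dirichlet draws with
  concentration 0.3 (positives) vs 0.5 (negatives) over 32 tissues —
  chosen in closed form so the expected TSPS (~1.33 vs ~1.01 bits)
  matches the reported group means; housekeeping genes keep all
  tissues strictly positive, others have 1–5 tissues silenced;
- count features are Poisson (domain number 3.33 vs 1.44, reaction
  0.04 vs 0.46, pathway 6.13 vs 0.97), age is 1 + Binomial(15, p)
  matched to the group means, evolutionary rate is Gamma-distributed,
  SNP counts are class-identical (the polymorphism ratio shows no real
  group difference);
- the PPI network is preferential-attachment (m = 4) with a mild extra
  edge rate for positives and self-loops for self-interacting
  proteins; the signaling network is preferential-attachment over the
  signaling molecules with positives steered to hubs (degree²-weighted
  slot assignment), elevating their degree and betweenness; TF
  indegree is Poisson (7.48 vs 2.96) over the TF pool;
- sequences are i.i.d. residue draws from a background composition
  with a weak tilt for positives (more tiny/small/aromatic, fewer
  basic residues), so sequence features separate weakly, in the
  reported directions.

Everything descends from one master seed through spawned substreams:
identical configurations produce byte-identical bundles, written in
the same TSV/FASTA formats the pipeline reads.

What the generator does **not** emulate: feature dependence beyond the
class label (real annotations are correlated — transmembrane proteins
are hydrophobic, signaling hubs are tissue-specific), homology
structure (sequences are i.i.d., so redundancy removal is exercised on
dedicated fixtures instead), realistic protein grammar (no domains,
motifs or composition autocorrelation), and database noise
(mislabeled or missing annotations). Passing the recovery and AUC
checks therefore demonstrates the statistical machinery is correct and
well calibrated — not that the quoted real-data AUCs would be
reproduced; those depend on curated TTD/DrugBank/GtoPdb/Swiss-Prot
extracts that are out of scope.

## Numerical choices and degenerate inputs

- Ambiguity codes: B→D, Z→E, U→C, X neutral (zero hydropathy, zero
  charge, non-ionizable) for GRAVY/pI/disorder; class membership of B
  and Z follows the published class table.
- pI bisection: 200 iterations max, stop at |charge| < 1e−3; the
  charge curve is strictly decreasing so the root is unique.
- Equal-frequency bin edges come from `numpy.quantile`; duplicate
  quantiles (heavily tied features) are collapsed, so `k` adapts.
- Empty-both-class bins with `alpha = 0` get LR = 1 (no evidence
  either way); empty-negative bins are infinite there, which is why
  `alpha = 0.5` is the default.
- Ties in genome ranking break by protein id; ties in mRMR by feature
  name — all outputs are bit-reproducible for a given seed.
- Coordinates are 0-based half-open internally (PEST and disorder
  segments); reports are 1-based only where explicitly human-readable.
- Cross-validated AUC of a signal-free (null) genome sits slightly
  below 0.5 (~0.43–0.50 at 120 labeled proteins): a held-out protein's
  own count is missing from its class's frequency estimates, the usual
  pessimistic bias of plug-in models under CV. The bias shrinks with
  sample size and is well inside the ±3 SD replicate band used to
  check null behavior.
- Recovery assertions on synthetic data are restricted to flags whose
  binomial sampling noise at the design size (100 positives) can
  resolve a 25% band — fixed a priori as 2.5 × delta-method SD of
  log LR <= log 1.25. Rarer flags (e.g. GPCR at 5% prevalence) are
  reported but not asserted: their sampling noise alone exceeds the
  band under any correct implementation.

## Problem sizes

Default experiment sizes are chosen to keep a full run on one CPU in
well under a minute while preserving the design of the original
protocol: 5000 proteins with 100 positives for the recovery and CV
experiments (100 negative replicates of 100, 10 folds), a 1500-protein
genome with 60 positives and 30 replicates for the null control, and a
20 × 20 replicate grid for the script's independent test (the full
protocol's grid is 100 × 100; the mean is unchanged, only its SD
estimate is coarser).

## Known limitations

- The LR model assumes feature independence given the class; the mRMR
  step reduces but does not eliminate redundancy among selected
  features, so combined LR magnitudes overstate the evidence when
  correlated features enter (ranks are affected less).
- Score grades are heuristics on an uncalibrated LR scale.
- Signal peptides, transmembrane regions, domain counts, ages,
  evolutionary rates and network edges are consumed as inputs; the
  package does not predict or curate them.
- The greedy homology filter depends on id order (deterministic, but a
  different order can keep a different non-redundant subset).
- Betweenness for directed networks is out of scope (the TF network
  contributes only in/out-degree).
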