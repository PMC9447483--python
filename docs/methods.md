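# Methods

`zwtools` implements the computational core of a female-heterogametic (ZW)
sex-chromosome characterization: finding W-linked sequence from comparative
read depth, dating ZW evolutionary strata from gametolog divergence,
profiling nucleotide/repeat composition, quantifying retroelement refugium
and toxicity signals, and summarizing W-linked gene-content evolution. This
note records the models, parameter choices and numerical conventions, and
what the synthetic-data generators do and do not emulate.

## Coverage model and W-linkage classification (`sexlink`)

A female carries one Z and one W; a male carries two Z. With per-sex depths
normalized by the autosomal median, the log2 female:male ratio (log2FM) has
analytic expectations of 0 (autosomes, PAR), −1 (Z) and, with a male
W-mapping background fraction b, log2(0.5/b) for W windows (b = 0.125 gives
the conventional "~2").

Two classifiers are implemented:

* **log2FM threshold** — W iff log2FM ≥ 1 (strict ≥). Z and autosomal bands
  (defaults [−1.5, −0.5] and [−0.25, 0.25]) are package additions for
  convenience; only the W rule carries scientific weight.
* **IQR outlier rule** — W iff the female share of normalized depth,
  f = F/(F+M), strictly exceeds Q3 + 1.5×IQR of the f distribution.
  The share statistic (autosomes 0.5, Z 1/3, W ≈ 0.8) is what makes an
  *upper*-outlier fence detect W windows; a fence on female normalized
  depth alone could not, since W windows sit at half the autosomal female
  depth. Quartiles use linear interpolation (type 7, the numpy default).

Zero-depth handling: log2FM takes a pseudocount (default 0.05 in
median-normalized units) so W windows with zero male depth stay finite; all
analytic identities quoted above hold at pseudocount 0. `calibrate` scores
calls against truth labels as power = TP/(TP+FN) over truth-W units and
FPR = FP/(FP+TN) over the rest. Scaffold-level calls are either computed
directly from per-scaffold depths or rolled up from windows by majority
vote with ties → ambiguous (the conservative choice).

## Depth noise model (`simulate`)

Window depth is generated as a negative-binomial read count converted back
to mean reads/bp. Reads are 150 bp and the NB size parameter is specified
per 1-kb tile; a window of length L therefore draws a count with mean
`depth·L/150` and size `dispersion·L/1000` (the distribution of a sum of
independent per-tile NB counts). This keeps the marginal overdispersed
relative to Poisson (var/mean ≈ 4 at the defaults: depth 30, dispersion 10,
10-kb windows) while representing local, tile-scale mappability noise that
partially averages out across a window — the regime in which both
classifiers operate at small false-positive rates, as they do on real
mapping data. `dispersion = inf` gives the exact noise-free limit used by
the analytic tests. Defaults: mean_depth 30, dispersion 10,
male_w_background 0.125 (a modeling choice — the background mapping rate
implied by "log2FM ≈ 2 on W" is not independently known — exposed as a
parameter).

## Gametolog divergence: NG86 with Jukes–Cantor correction (`divergence`)

dN/dS between aligned gametolog CDS pairs uses the Nei–Gojobori (1986)
counting estimator rather than an ML codon model: the downstream dating
chain consumes only stratum mean/median dS, for which the counting
estimator is standard, fully specifiable and exactly testable against
brute-force enumeration. Pre-computed dS/dN tables can be supplied instead
wherever a frame of pairs is accepted.

Conventions:

* Synonymous sites per codon = (number of the 9 single-nucleotide changes
  that are synonymous)/3, with changes creating stop codons counted as
  nonsynonymous; sites are averaged over the two sequences.
* Codons differing at k > 1 positions are resolved by enumerating all k!
  substitution orders, discarding pathways through stop codons, and
  averaging difference counts with equal weights (classic NG86, no
  transition/transversion weighting). In the degenerate case where every
  pathway is blocked, all pathways are used and steps touching a stop count
  as nonsynonymous.
* Gapped or ambiguous codons are dropped pairwise; a trailing stop pair is
  dropped; internal stops are an input error.
* dS = −¾·ln(1 − 4pS/3) (likewise dN); pS or pN ≥ 0.75 flags the pair
  saturated (NaN distances) rather than silently truncating.

Pair filtering retains 0.001 ≤ dS ≤ 2 (bounds inclusive), applied before
strata assignment.

The codon-pair simulator evolves a W copy from a random stop-free ancestral
sequence by uniform single-nucleotide proposals accepted with probability 1
(synonymous) or ω (nonsynonymous), rejecting stop-creating proposals, until
the accepted synonymous count reaches `S_sites·target_dS`. Because
proposals are uniform, the Jukes–Cantor correction recovers the realized
substitution count and the NG86 estimate recenters on the target
(recovery within ±0.05 for targets ≤ 0.5 at 50 pairs × 500 codons; ω
recovered within ±0.1 at the neutral limit). Divergence is placed on one
lineage only; dS is pairwise, so only total divergence matters.

## Strata assignment and dating

With explicit Z-coordinate breakpoints (the recommended, exactly
reproducible path) genes are binned by anchor position; with `k_clusters`,
1-D k-means (100 restarts, fixed seed) clusters anchors and clusters are
relabelled along the chromosome. Stratum labels order clusters by mean dS,
higher = older ("S1" oldest); clusters can be merged into
older/recent superstrata. Whether filtering precedes clustering is a free
choice; this package filters first.

The rate model: mu_A from median autosomal ortholog dS over twice the split
time (0.94/(2·167 Myr) = 2.81e-9/site/year, reported at 2 s.f. as 2.8e-9);
combined ZW rate = mu_A·z_ratio + mu_A·female_fraction with defaults
z_ratio 1.1 (male-biased mutation) and female_fraction 0.25 (conservative
W rate, female germline only). Each component is rounded to
`RateModel.rounding` significant figures (default 2) before summation —
the printed chain 3.1e-9 + 0.7e-9 = 3.8e-9 only holds under component
rounding — while `rounding=None` gives the exact sum, which is what the
4-fold-degenerate chain uses (2.4e-9 → 2.64 + 0.60 = 3.24e-9). Time =
dS/rate; with dS = 0.33 the two rates date the older strata to 87 and
102 Ma.

## Composition (`composition`)

GC = (G+C)/(unambiguous bases); CpG = CG dinucleotides / unambiguous
dinucleotide positions, single strand, overlapping positions counted
(the denominator convention is explicit because per-base alternatives
exist and change the scale ~2-fold). Same-family repeat intervals are
merged before fraction computation; different families may double-count
bases, matching RepeatMasker-style annotations. Terminal short windows are
retained and flagged, with fractions over actual length. Element ages use
the Kimura 2-parameter distance d = −½·ln((1−2P−Q)·√(1−2Q)); with CpG
correction, both positions of every consensus CpG are excluded before
counting P and Q (the calcDivergence convention). GC3 = G+C at third codon
positions over unambiguous third positions; the Z-vs-W GC3 comparison uses
Welch's t (GC3 distributions are approximately normal) plus the strict
W > Z fraction.

Partial rank correlations (mdg4-density vs GC controlling CpG and
non-focal repeat fraction) are computed from the inverse of the Spearman
correlation matrix with a t-approximation p-value at df = n−2−k, and are
cross-checked against an independent implementation in the test suite.

## Refugium and toxicity (`refugium`)

Expected repeat content per class is length-proportional:
exp_c = total_obs·len_c/Σlen. RI_c = (obs_c − exp_c)/exp_c; uniformity is
tested by Pearson χ² with df = 2 over {autosome, Z, W}. Identical formulas
serve bp totals (repeat families) and element counts (fl-LTRs). PAR bp is
assigned to the Z class by default (configurable upstream of
`ChromClassTotals`). Toxicity index = (2n_het − 2n_hom)/2n_hom with
2n_het = 2A + Z + W and 2n_hom = 2A + 2Z; zero means no sex bias.
P-values are reported to machine precision (no "<2.2e-16" floor).

## Gene content (`gene_content`)

Copy number: per-female relative value 2·(gene depth / autosomal median)
(the ×2 haploidy correction scales a single-copy W gene to 1), averaged
across females; the duplication flag uses a 1.5-copy threshold (the
midpoint rounding boundary; configurable). Decay rate =
(n_Z − n_W)/stratum age in genes/year; gene gain (n_W > n_Z) is flagged,
not rejected. Stratum enrichment is a two-sided Fisher exact test.
Translocation calls are conservative: a candidate autosome-to-W
translocation requires *no* Z gametolog *and* a positive outgroup
(Anolis) ortholog off chromosome 6 (the chromosome ancestrally homologous
to the caenophidian ZW pair); genes without an outgroup hit are "unknown".
Expression detection is the raw-count rule (count > 0 in ≥ 1 sample of a
sex); female-specific = detected in females and not males; TPM values are
length-normalized rates scaled to 1e6 per sample. Formal differential
expression is out of scope (an external DE table can be joined on gene id).

## What the simulators do and do not emulate

The generators reproduce the *statistical structure* the analyses assume:
sex-specific copy number with overdispersed depth noise, codon pairs with
controlled dS/ω, uniformly placed non-overlapping repeat intervals with
per-class enrichment and family-specific GC, and Poisson expression
counts. They do not emulate read-level artifacts (mappability structure,
GC bias in coverage, paralogous mapping), assembly fragmentation,
selection heterogeneity along genes, repeat nesting/fragmentation, or
codon-usage bias. Passing calibration and recovery tests therefore
validates the estimators and their implementations under the stated
models — not classifier performance on real mapping data, whose absolute
power/FPR (e.g. the chicken experiment's 0.954/0.0049) depends on those
artifacts; only the *ordering* of the two classifiers' false-positive
rates is asserted, and it is reproduced.

## Problem sizes and determinism

Default test/acceptance problem sizes: 10,000 × 10-kb windows for
calibration; 50 pairs × 500 codons per stratum (100 Mann–Whitney
replicates) for divergence recovery; ~1-Mb chromosomes for repeat and
composition recovery; 1,000 random 200-codon pairs for oracle equivalence.
These sizes put simulation standard errors well inside the asserted
tolerances. All generators take explicit integer seeds
(`numpy.random.default_rng`) and fixed seeds give byte-identical outputs.

## Known limitations

* NG86 understates divergence relative to ML codon models at high dS and
  ignores transition/transversion and codon-frequency bias; per-stratum
  *means* at dS ≤ 0.5 are unaffected in the tested regimes.
* The recent-stratum printed dates (40–47 Ma) are not exactly recoverable
  from a rounded stratum mean of 0.16 under either rate (42–49 Ma); the
  unrounded mean was presumably used upstream, so no exact claim is made.
* The IQR classifier's FPR depends on the window-class mixture through the
  adaptive fence; it is only meaningfully comparable to the fixed
  threshold on mostly-autosomal layouts like those used here.
* `ChromClassTotals` treats classes as exchangeable labels; it does not
  validate that observed bp fit inside class lengths.
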