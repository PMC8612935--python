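# Methods

## Contact quantification

Detection of window *x* across *n* NP samples gives a marginal frequency
p(x) = detections/n; joint detection of a pair gives p(x,y).  Contact
strength is normalized pointwise mutual information,

    PMI  = ln( p(x,y) / (p(x) p(y)) ),     NPMI = PMI / (−ln p(x,y)),

computed with the natural log (the ratio is base-invariant).  NPMI is 1 iff
the pair always co-segregates (p(x,y) = p(x) = p(y)), 0 under exact
independence, and negative for avoidance.  Entries with p(x,y) = 0, a zero
marginal, or p(x,y) = 1 (the normalizer vanishes) are undefined; they are
carried as NaN and excluded from every downstream mean.  No matrix balancing
(ICE/KR) is applied — NPMI already conditions on the marginals.

Distance normalization converts each off-diagonal of a chromosome's NPMI
matrix to Z-scores using the population standard deviation (ddof 0 — this is
a normalization, not an inference step).  Diagonals with fewer than two
finite entries or zero spread map to zeros (a relative tolerance of 1e−12
guards against float jitter on constant diagonals).

Differential contacts between datasets A and B: windows below the 2nd
percentile of the per-window detection-frequency distribution (computed over
detected windows, per chromosome, in either dataset) are removed from both;
pairs are kept within 0.5–5 Mb (a 0.05 Mb lower bound is available by
configuration) and with NPMI > 0.15 in at least one dataset — the laxer
reading, which retains contacts lost entirely in one cell type; D = z_A −
z_B, and the top 5% by D and by −D form the A- and B-specific sets.  When D
is identically zero the sets are empty (ranking ties would be arbitrary).
Aggregate pileups average Z over each contact's (2r+1)² patch (r = 4 bins,
truncated at matrix edges) pooled per chromosome, then average the
per-chromosome means.

## Window calling

For each sample, candidate thresholds are the integer percentiles of its
strictly positive coverage values; percentile 0 is taken as threshold zero,
i.e. every covered window positive.  (With strict detection, cov > t, a
threshold equal to the minimum positive value could never yield a fully
positive call on uniform coverage; the zero baseline makes the grid's lower
end well defined.)  The chosen percentile minimizes the orphan-window
fraction — positives flanked by negative neighbours, a proxy for sporadic
background — with ties broken toward the lowest percentile, which retains
the most windows.  Chromosome-edge positives with a negative inner neighbour
count as orphans (conservative).  QC thresholds are strict: orphan fraction
< 0.70, mapped reads > 50,000, max Jaccard to platemates < 0.4.

## Insulation and boundaries

The insulation score of bin *i* at scale *k* bins is the mean of finite NPMI
values in the square rows [i−k, i−1] × columns [i+1, i+k]; bins within *k*
of a chromosome end are missing.  The ladder is 100–1000 kb in 100-kb steps
(k = 2…20 at 50-kb bins); boundaries are called at 500 kb.

Boundary candidates are strict local minima, missing-aware; plateaus of
equal values count once with the first bin as centre (no prominence filter
by default).  Candidates whose 3-bin intervals touch or overlap (centres ≤ 3
bins apart) merge, keeping the bin with the lowest insulation.  An optional
`min_prominence` requires the minimum to sit at least that far below the
lowest of the two highest levels reached before the profile next drops below
it (the standard topographic-prominence notion).  On simulated matrices the
planted-junction dips have prominence ~0.05–0.3 NPMI units while
sampling-noise minima stay below ~0.01 at 500 samples, so recovery analyses
here use `min_prominence = 0.02`; at any finite sample count some
noise-level strict minima are unavoidable, so a caller with no prominence
filter necessarily reports them too.

Boundary comparison across datasets: two 150-kb boundaries are the same
feature when their intervals touch or overlap, different when separated by
at least one full genomic bin (centres ≥ 200 kb apart at 50-kb bins).
Clusters are the transitive closure of this pairwise rule (the rule itself
is not transitive), which yields deterministic UpSet-style exclusive
categories.  Chromosome Y is excluded by default.

## Compartments

Per chromosome: O/E divides each diagonal by its finite-entry mean; the
correlation matrix C is the pairwise-complete Pearson correlation between
O/E columns, after dropping bins with under 50% finite entries; PCA (column
centring + SVD) is run on C and, among the first three components, the one
with the best |Pearson r| to GC content is kept, signed so that r > 0.
Positive bins are A (open, GC-rich), negative B; exact zeros are left
unlabelled rather than assigned a side.  A-values are rescaled by the
chromosome's maximum and B-values by |minimum|, so tracks span (0,1] and
[−1,0).  Whole chromosomes are used (no arm splitting).  Transition classes
(A→A, A→B, B→A, B→B) are assigned where both datasets are defined, with an
optional replicate-consensus pre-filter.

## Melting scores

Genes longer than 300 kb that fully cover at least 8 bins are tested.  Per
dataset, the insulation values over the gene's bins at all 10 scales are
pooled into one empirical distribution (~10× the bin count).  Melting —
insulation loss in the query — is tested with the one-sided two-sample KS
statistic D⁺ = sup(F_query − F_ref).  The p-value is the asymptotic
exponential form with Hodges' finite-sample correction of the exponent,

    p = exp(−2z² − 2z(m + 2n̄)/(3·sqrt(m·n̄·(m+n̄)))),   z = D⁺·sqrt(mn̄/(m+n̄)),

(m ≥ n̄ the two pool sizes), which tracks a label-permutation test within
Monte-Carlo error down to pools of a dozen values; the uncorrected bound
exp(−2z²) overstates p noticeably at these sizes.  An exact permutation
p-value is available for small pools.  p is floored at 1e−300 (scores cap at
300), Bonferroni-corrected by the number of genes actually tested in the
run, and −log10-transformed; score > 5 (corrected p < 1e−5) calls melting.

**Raw vs rank pooling.**  By default raw insulation values are pooled, which
is also what the two-CDF comparison implies when the datasets share a
calibration.  A percentile-rank mode (per scale, per dataset, genome-wide)
exists for datasets with very different intensity scales, but it amplifies
small uniform level shifts whenever genome-wide insulation values cluster
tightly — on synthetic data this turned ~3% null false-positive calls into
~25% — so rank mode should be reserved for strongly mismatched inputs.

Trans–cis ratios: at 250-kb bins, bins detected in under 3% or over 75% of
samples are dropped; each surviving bin's ratio is the arithmetic mean NPMI
to all other-chromosome bins over the mean NPMI to same-chromosome bins
(diagonal excluded); gene values are medians over gene bins.  Length-scaled
reads per million: overlaps / ((length·1e−6)·(total·1e−6)).

## TF feature pairs

A window carries motif f when an accessible peak supported by ≥10% of single
nuclei overlaps the window and contains ≥1 hit of f (motif scanning itself
is external; hits arrive as intervals).  For F motifs all C(F,2)
heterotypic + F homotypic unordered pairs are scored on a differential
contact set: a heterotypic pair is present on a contact when one motif sits
on each window (either orientation); homotypic pairs need the motif on both.
Enrichment is (count_A/total_A)/(count_B/total_B) with an infinity sentinel
when count_B = 0; information gain is the base-2 entropy of the direction
label minus its presence-conditional entropy.  The shortlist is the union of
top-10 by information gain and top-5 by each direction's enrichment, ties
broken lexicographically.  Network edges keep pairs present on ≥20% of a
cell type's contacts, weighted by count; community detection is left to
standard graph libraries.

## In-silico GAM

Each structure is a 3D Gaussian random walk (step σ = 1 per coordinate)
over `n_windows × beads_per_window` beads.  Three planted features:

- **step factor** per block scales its steps; a factor of 2 doubles the
  block's spatial extent ("melting" / decondensation);
- **compaction** contracts a block's beads toward the block centroid
  (default 0.6 in the study configuration), creating TAD-like
  self-association with clean junctions;
- **compartment labels** pull each labelled block toward one of two hub
  points placed at the chain centroid ± 0.5 R_g along a random axis per
  structure (pull fraction 0.7).  Hubs must be placed explicitly: means of
  same-label block centroids nearly coincide on a random walk and give no
  A/B contrast.

Slicing mirrors the GAM protocol: per NP, a structure is drawn uniformly, a
slab normal uniformly on the sphere, and the slab centre uniformly over the
structure's projected extent; the slab width is a fixed fraction (default
0.05, mirroring ~220-nm sections of μm-scale nuclei) of that extent.  Slabs
may miss most of the polymer — empty NPs are allowed, as in real data.  A
window is detected when any of its beads falls in any of the sample's 3
pooled slabs.  For a locus at the centre of the nucleus this gives detection
probability ≈ thickness per NP and 1−(1−p)³ per 3-NP sample, which the tests
verify against the simulation.  The ground-truth contact matrix used for
reconstruction checks is the ensemble mean of 1/(1+d) over window-centroid
distances d — any monotone proximity transform would do; this one is fixed
for reproducibility.

**Study configuration.**  The canonical synthetic chromosome is 200 windows
of 50 kb (10 Mb) in ten 1-Mb blocks, 10 beads per window, 300 structures per
ensemble (within the "up to 450 configurations" scale of polymer-model
ensembles for such loci), 500 samples of 3 NPs.  Melting analyses use the
configuration without compartment labels: hub pulls add between-ensemble
variability in long-range contacts that contaminates the insulation null
when two independent ensembles are compared.  The melted gene is one 1-Mb
block with step factor 2; unperturbed blocks serve as control genes.

**What the simulator does not emulate** — and hence what passing tests do
not establish about real data: excluded-volume and polymer-melt physics
(blocks are independent Gaussian walks, not equilibrated chains), sequencing
depth and mappability variation (detection is geometric and noise-free given
the slab), chromosome territories with multiple chromosomes per nucleus,
replication/copy-number effects, and cross-well contamination.  QC metrics
on simulated data are therefore near-ideal by construction; the simulator
validates algorithmic correctness and statistical calibration, not
robustness to experimental artefacts.

## Numerical and interface choices

- Coordinates 0-based half-open everywhere (BED convention); chromosome
  names matched literally; segregation TSV dialect fixed to
  `chrom/start/stop` + sample columns, gzip transparent.
- Undefined matrix entries are NaN throughout; persisted archives store an
  explicit mask.  Reals round-trip text formats at ≥9 significant digits.
- All randomness flows from one seeded `numpy` Generator per run; identical
  seeds give identical ensembles, slices and tables.
- The 99th-percentile colour scaling is applied only in the plotting
  command, never to stored values.
- Whether chromosome Y windows are dropped before matrix construction is
  exposed as a flag on boundary comparison (`exclude_chroms`), the one place
  the convention matters downstream.

## Known limitations

- The differential-contact NPMI floor (0.15, "in at least one dataset") and
  the 0.5-Mb minimum distance are the defaults; figure-style 0.05-Mb
  analyses must opt in.
- Melting scores between datasets with very different NP counts rely on the
  raw-pooling comparability assumption above; rank mode trades that
  assumption for sensitivity to level shifts.
- The asymptotic KS p-value is accurate to permutation-test resolution for
  pools ≥ ~10 values per side; below that, use the permutation option.
- Boundary calling reports every strict local minimum by default; users
  comparing noisy matrices should set a prominence appropriate to their
  insulation scale.
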