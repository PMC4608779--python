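# Methods

`orthotime` compares early differentiation time courses of human and mouse
embryonic stem cells (hESC / mESC) measured on two unrelated microarray
platforms, and relates expression conservation to promoter binding-site
(TFBS) content.  This note describes the models and procedures, the
synthetic study design used for validation, and the numerical choices that
were genuinely open.

## Study design assumed by the pipeline

Human cultures are profiled at days 0, 3, 6, 9, 12, 15, 18 and 21 (8 time
points) and mouse cultures at days 0–7 and 10 (9 time points), three
biological replicates each, with day 0 the undifferentiated reference.
Probes (several per gene) carry platform-specific offsets and gains, so
absolute signals are not comparable across species; all cross-species
statements are about profile *shape*.

## Preprocessing

* **Representative probe.** For each gene the probe whose replicate-mean
  profile has the largest sample variance across days is selected
  (`criterion="range"` uses max − min instead).  Variance is the default
  because it is less sensitive to a single aberrant time point.  Exact
  ties go to the lexicographically smallest probe id, which makes the
  selection order-independent.
* **Standardization.** Profiles are replicate-averaged, mean-centered and
  scaled to unit sample SD.  Centering is added on top of unit SD because
  every downstream statistic (Pearson correlation, k-means on unit
  vectors, PCA) is location-invariant, and centered profiles plot
  comparably.  Zero-variance profiles carry no shape information and are
  excluded with a logged reason.
* **Presence calls.** A gene's call on one array is the maximum of its
  probes' detection calls under P > M > A; the gene is *expressed* when at
  least `k` arrays (default 3, configurable 3–5) call it P.  M counts as
  not-present.
* **Upregulation.** A gene is upregulated at day *t* when its replicate
  mean exceeds the day-0 mean by at least log2(fc) (default fc = 2).
  Term enrichment of the upregulated union is an upper-tail
  hypergeometric test on a flat gene→term table.
* **Differential-regulation selection.** An ortholog pair enters the
  comparison when, in *both* species, some day's replicate mean deviates
  from the gene's grand mean by more than 0.5 log2 units (strict
  inequality; threshold configurable).  No quota on the number of
  selected genes is imposed.

## Profile comparison

Profiles on different day grids are compared after linear interpolation
onto a common grid of 11 equidistant points per species interval
(default human [0, 21], mouse [0, 10]).  Linear interpolation is the
simplest monotone scheme and reproduces measured days that fall on the
grid.

Significance of a Pearson correlation r over NP measured points uses

    t = r * sqrt((NP − 2) / (1 − r²)),   df = NP − 2,  two-tailed.

Interpolation adds no information, so NP is the smaller of the two
species' counts of *measured* days inside the compared intervals, never
the size of the common grid.  This yields the two-decimal p < 0.05
boundaries r = 0.71 at NP = 8 and r = 0.67 at NP = 9.  A profile that is
constant inside the compared window (possible when a late-peaking gene is
windowed early) is assigned r = 0 — no shape evidence.  Two correlations
are compared with the Fisher transform z = atanh(r),
Z = (z₁ − z₂)/√(1/(n₁−3) + 1/(n₂−3)).

**Time-scale scan.** Candidate human interval ends {12, 15, 18, 21} days
are each correlated against the fixed mouse interval [0, 10]; the
candidate with the largest fraction of positively correlated pairs wins,
with ties broken by the fraction significant and then by the longer
interval.  Inside the scan, significance uses one fixed reference NP
derived from the full measured grids for every candidate.  Letting NP
float with the candidate window would handicap short windows (fewer
measured human days → a harsher threshold) and systematically bias the
tie-break toward 21 days; a single threshold across intervals keeps the
candidates commensurable.

**PCA eigenvector matching.** Selected pairs form a matrix of 22 columns
(human 11-point grid ‖ mouse 11-point grid); PCA is run on the
mean-centered columns without re-scaling (profiles are already unit-SD).
Each eigenvector is split into its species halves and the halves are
correlated; diagonal pairs (i, i) for i ≤ 7 plus the (1, 2) pair are
reported.  Because an eigenvector's sign is arbitrary, |PCC| is the
headline value and the raw signed value is kept in a separate column.

## Clustering

Standardized profiles are clustered with k-means.  On unit-SD vectors,
squared Euclidean distance is an affine function of the Pearson
correlation, so k-means groups by shape.  More elaborate partition
samplers (e.g. Chinese-restaurant-process clustering) offer no advantage
here: shape clusters of standardized profiles are compact and convex, and
the downstream summaries are robust to the choice of clustering method.
Seeding modes: cluster the mouse profiles (default), the human profiles,
or the concatenated 11+11-point profiles of both species
("co-clustering"); orthologs inherit labels.  `k="auto"` maximizes the
mean silhouette over k = 2..12.  Clusters below the minimum size
(default 30) are dissolved into the nearest remaining centroid; labels
are renumbered 1..K by decreasing size.  Per cluster and species the
pointwise mean ± SD band on the common grid is reported, plus the PCC of
the two species' mean profiles and the sorted correlation-vs-percentile
curve.

## Promoter TFBS analysis

* **Scanning.** Both strands of each promoter are scanned with each PWM's
  log2-odds matrix (pseudocount 0.01 per cell, background base
  frequencies estimated from the background promoter set).  A window is a
  hit when its score reaches a fraction *f* (default 0.85) of the motif's
  maximum achievable score.  `N` bases score −∞.  Overlapping hits are
  all counted; no greedy collapsing.
* **Background.** The *n* (default 500) expressed genes with the smallest
  representative-probe profile variance — expressed but unregulated.
  Optional GC correction resamples the background into 5% promoter-GC
  bins matching the foreground histogram.
* **Density enrichment.** Upper-tail hypergeometric test on site density:
  population = scannable positions of foreground plus background
  ((L − w + 1) × 2 strands per promoter), successes = all hits, draws =
  foreground positions, observed = foreground hits.  This parametrization
  makes "density" exactly testable and oracle-checkable.
* **Assignment.** A motif is assigned to a gene group when p ≤ α
  (Bonferroni default α = 0.05 / library size) *and* at least 40% of the
  group's promoters carry ≥ 1 hit.  The coverage gate suppresses
  assignments driven by a few promoters with many sites.
* **Random-group null.** Size-matched random groups of expressed genes
  yield an empirical p-value distribution; the reported empirical cutoff
  is the smallest null p-value observed.  Note two statistical facts,
  both visible in validation: (i) the hypergeometric p-value is discrete
  and overlapping windows are weakly dependent, so at dense hit rates the
  test is mildly conservative; (ii) random groups share one background
  set, so their p-values are positively correlated — calibration checks
  therefore pool several independent fixtures.
* **Reports.** Per cluster: expression PCC of mean profiles vs the
  hypergeometric overlap p-value of the two species' assigned motif
  lists (similar expression / similar promoters plane).  Per motif: the
  number of clusters per species with density p below a strict cutoff
  (default 10⁻⁹, log2 ≈ −29.9), and the cross-species correlation of
  these counts.

## Synthetic study design

The generator emulates the two-platform, two-timescale design with known
ground truth.

* **Shapes.** Cluster templates are piecewise linear in *mouse time*
  s ∈ [0, 10]: `down`, `up`, `delayed_down` (flat, then down from
  s_max/2), `peak:d` (triangular bump at day d, half-width 2 days), and
  `flat` for non-regulated genes.  The default set
  (down, up, peak:2, peak:5, peak:8, flat) was chosen so that distinct
  standardized templates correlate at |r| ≤ 0.49 on the mouse grid;
  template pairs like down/delayed-down (r = 0.85) are not separable by
  any shape-based clustering and are not used together by default.
  A human day t maps to s = t / dilation (default dilation 2.1 = 21/10,
  matching the ~2× difference in population doubling time); beyond
  s = 10 the shape extends at its final value.
* **Heterogeneity.** Each gene deviates from its cluster template by a
  smooth random curve (5 knots across mouse time, amplitudes
  N(0, 0.2 log2)), shared between species for conserved clusters and
  drawn independently for the human side of divergent clusters.  This is
  the feature that makes the synthetic data behave like the real study —
  without it, every conserved pair correlates at ~1 under *any* candidate
  time scale and interval scans saturate.  Divergent clusters use a
  different template on the human side.
* **Measurement model.** value = 8.0 (baseline) + template·(amplitude/2)
  + gene deviation + probe offset N(0, 0.5) + replicate noise
  N(0, noise_sd); default amplitude 2 log2 units, noise 0.2.  Each gene
  gets 1 + Poisson(1.5) probes (capped at 5); probe 1 carries the full
  signal, later probes attenuate it by a uniform gain in [0.3, 1] —
  this creates the representative-probe selection problem.
  Silent genes (per-species Bernoulli, default 0.25) sit at a low flat
  baseline and receive A calls (P/M calls otherwise).
* **Promoters and motifs.** Random PWMs have one dominant base per column
  (probability 0.75–0.95); promoters are iid nucleotides at a set GC
  content.  Planted sites are sampled from the PWM but rejected until
  they score at least the scan-threshold fraction of the maximum
  (consensus fallback after 100 draws), so planted occurrences are
  recoverable at the matching threshold by construction.  Conserved
  clusters receive the same motif in both species; divergent clusters a
  different one on the human side; flat clusters none.

**What the generator does not emulate:** probe-level CEL intensities,
array spatial artifacts, correlated noise across genes, realistic
promoter composition (CpG islands, repeats), motif clustering into
cis-regulatory modules, and GO term structure.  Passing tests therefore
demonstrate that the statistics recover planted structure under the
stated noise model, not that they would behave identically on arrays.

## Validation sizes and expectations

Validation problem sizes were chosen so the whole suite runs in a few
minutes: time-scale recovery uses 600 single-probe gene pairs per study
(the fraction-positive argmax needs a few hundred pairs to resolve
adjacent candidates; a full array study yields a few thousand), cluster recovery
250 genes × 10 seeds, motif recovery 20 fixtures of 350 genes with a
20-motif library, and null calibration pools 12 independent fixtures of
30 random groups × 20 width-7 motifs scanned at f = 0.65 — a sparser
regime than the default f = 0.85 so that hit counts are large enough for
the discrete hypergeometric p-value to be nearly continuous, yet sparse
enough that overlapping-window dependence stays negligible.

## Known limitations

* The dilation estimate is only as fine as the candidate grid
  (12/15/18/21 days); adjacent candidates (dilation 1.8) are
  intrinsically close and a noisy study occasionally prefers 21.
* Hypergeometric density p-values treat scan positions as exchangeable;
  overlapping windows violate this slightly, making the test mildly
  conservative at permissive thresholds.
* k-means assumes roughly balanced, convex shape clusters; the silhouette
  criterion can merge templates whose standardized profiles correlate
  strongly.
* The `peak:8` template is barely sampled by the mouse day grid
  (days 7 and 10 straddle the bump), a deliberate property of the design
  grid worth remembering when interpreting mouse-seeded results.
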