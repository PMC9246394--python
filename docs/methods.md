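# Methods

This package implements the post-segmentation spatial analysis of
multiplexed immunofluorescence images of lupus nephritis (LN) kidney
biopsies: evaluating instance segmentations at the object level,
combining staining rounds into T-cell phenotypes, comparing per-ROI
immune-cell densities between renal-outcome cohorts, discovering and
classifying cellular neighborhoods, quantifying nearest-neighbor class
structure, and measuring the proximity of cells and neighborhoods to
renal structures.  Because the underlying patient images are not
distributable, a synthetic-tissue generator supplies cohorts with the
statistical structure the analyses assume; every claim the test suite
makes is therefore a claim about recovery of planted structure, not about
patient data.

## Coordinate conventions and units

Cell positions are sub-pixel `(x, y)` centroids with `x` the column and
`y` the row, origin top-left.  Distances between cells are Euclidean
centroid-to-centroid in pixels unless an operation states microns; the
two imaging modes have fixed pixel sizes (HR fields of view: 1024x1024 px
at 0.1058 um/px; HMP whole sections: 0.221 um/px).  A pixel `(x, y)`
covers the unit square `[x, x+1) x [y, y+1)`; structure distances are
measured to pixel centers `(x+0.5, y+0.5)`.

## Detection evaluation

Predictions and ground truth are matched one-to-one: predictions with
confidence below 0.3 are rejected first (they produce no false positive —
their truth simply stays eligible); candidate pairs require mask IOU
strictly greater than 0.25 and, by default, class agreement; surviving
candidates are accepted greedily in descending IOU, ties broken by
`(pred_id, truth_id)`.  The greedy rule is a package choice — standard in
detection evaluation and deterministic; an optimal (Hungarian) assignment
would differ only in contrived tie structures.  A prediction that
overlaps a truth above threshold but disagrees in class is a false
positive, and the truth becomes a false negative only if no other
prediction claims it.  Precision, recall, and F1 use the convention that
a zero denominator yields 0; the IOU of two empty masks is an error
rather than 0.

## Densities and bootstrap inference

Densities are counts per ROI (fixed-area fields make counts proportional
to densities).  Outcome groups are compared per class by two-sided
Mann-Whitney U with Bonferroni correction over the declared family.
Because the cohorts are imbalanced in both patients and ROIs per patient,
a bootstrap resamples each group's ROI pool with replacement — 1000
iterations of 200 ROIs/group (2-group) or 150 ROIs/group (3-group) — and
summarizes each pairwise difference in group means by a percentile 95%
CI; a difference is significant when its CI excludes 0.  The percentile
CI (rather than BCa or normal-theory) is a package choice; the
calibration test shows it excludes 0 for 5% +- 2% of identical pools when
the pool size matches the resample size.  ROIs, not patients, are the
resampling unit; patient-level clustering is not modeled, so the CIs
understate patient-to-patient variance — a known limitation shared with
the resampling design the analysis mirrors.  In two-group analyses the
ESRD-current patients are pooled into ESRD+.

## Neighborhoods

Neighborhoods are DBSCAN clusters over centroids with epsilon 100 px (HR)
or 50 px (HMP) — both about 10.6 um, one cell body — and minimum size 2.
At minimum size 2 DBSCAN reduces exactly to the connected components of
the graph joining cells at distance <= epsilon, discarding isolated
cells; the test suite verifies this equivalence against a brute-force
union-find oracle.

Each neighborhood is described by 24 features, in fixed order: counts of
the five panel classes (5), their proportions (5), cell count (1),
convex-hull area in um^2 (1), density = count/area (1), pseudocount
ratios `(a+1)/(b+1)` for B:T, CD4+T:CD4-T, and lymphocyte:DC (3), mean
and SD of cell area in um^2 (2), mean cell eccentricity (1), hull aspect
ratio and circularity (2), maximum pairwise centroid distance in um (1),
mean within-neighborhood nearest-neighbor distance in um (1), and the
majority-class proportion (1).  Degenerate hulls (fewer than three
non-collinear centroids) fall back to a 1-px-wide strip along the
neighborhood diameter so all features stay finite.  When masks are
absent, cell area defaults to 50 um^2 (a typical lymphocyte) and
eccentricity to 0.  Distances and areas are in physical units so
features are translation-invariant and scale correctly with pixel size.

Archetypes are K-means classes over z-scored features.  The class count
is chosen by bootstrapping the within-cluster sum of squares: rows are
resampled, z-scored, and fit for each k; the chosen k is the one
preceding the first k whose mean marginal WCSS decrement falls below 10%
of the k=1 WCSS.  Archetypes are described by leave-one-out Welch t tests
(archetype vs pooled rest); the most positive statistics name the
archetype.  On planted six-archetype feature data this procedure selects
k=6 in >= 90% of seeded runs and recovers the partition with Rand index
>= 0.95.  On the default synthetic cohorts themselves the elbow
typically selects a smaller k: most detected neighborhoods are pairs and
triples whose feature vectors are dominated by degenerate-shape values,
which blurs the archetype structure.  This mirrors the fact that
archetype discovery needs either many large neighborhoods or features
informative at small sizes, and it is why the k-selection machinery is
validated on planted feature archetypes rather than on the raw cohort.

Two rule classifiers mirror the field definitions, with boundary
semantics exactly as worded: a **B-T (TLS-like)** neighborhood has at
least 20 cells (inclusive), at least one B cell and one CD4+ T cell, and
at least half (inclusive) of its cells B and/or CD4+ T; a **CD4-**
neighborhood has fewer than 20 cells (exclusive) with at least a quarter
(inclusive) of its cells CD4- T (the CD4- class in the HR panel, CD8+
or DN T in the HMP panel).  Per-patient prevalence is the count of
labeled neighborhoods divided by the patient's ROI count, compared
across outcome groups by Mann-Whitney with Bonferroni correction over
the labels tested.

## Proximity and structures

Nearest neighbors are found per frame (never across ROIs) by exact
KD-tree search with ties broken by the lower cell id; cohort differences
in the share of cells whose nearest neighbor belongs to a focal class use
the chi-squared test of independence without continuity correction,
Bonferroni-corrected over source classes.  No edge-effect buffer is
applied, matching the plain nearest-neighbor procedure.

The structure mask labels each pixel background / tubulointerstitium
(TI) / tubule / glomerulus with precedence glomerulus > tubule > TI.
The tissue mask is derived from a nuclear channel by gamma correction
(default 0.5), Gaussian smoothing (default sigma 8 px), min-max
normalization, and Otsu thresholding, followed by removal of small
components and holes; the normalization makes it invariant to global
intensity scaling.  These defaults are package choices and are exposed
in the parameters.  Cell-to-structure distance is the minimum Euclidean
distance from the centroid to any target pixel center (0 when the
centroid's pixel carries the target label), computed exactly with a
KD-tree over target pixels and verified against a brute-force scan.
Neighborhood-to-structure distance is the mean of member-cell distances
(robust to elongated neighborhoods; a centroid-based summary is a
one-line change), and rule-label groups are compared by Mann-Whitney
with Bonferroni correction.

## Synthetic-tissue generator

Cells are a superposition of a homogeneous Poisson background per class
and a Thomas-type cluster process per neighborhood archetype: cluster
parents follow a Poisson process with a per-archetype, per-outcome-group
intensity; each parent spawns a negative-binomial number of offspring
(minimum 2, so clusters are detectable) displaced by isotropic Gaussians
with sigma 5 um, keeping within-cluster gaps below the ~10.6 um
clustering radius.  Parents of the large B-T archetype can be anchored
within 40 px of glomerular boundaries, emulating periglomerular
aggregates.  Structure layouts place non-overlapping glomerulus discs
and tubule ellipses in a tissue canvas, with the tubule area driven
toward a requested fraction (default 0.30, against 0.03 for glomeruli),
so compartment ordering TI > tubule > glomerulus holds by construction.

Cohort defaults emulate the study design: 36 ESRD-, 14 ESRD+, and 5
ESRD-current biopsies, with mean ROI counts 12 / 19 / 32 per biopsy so
the smaller ESRD+ group contributes more ROIs — the imbalance the
bootstrap is designed to absorb.  The planted group effects are
directions, not published magnitudes (the source reports box plots
only): B intensity 2x higher in ESRD- than ESRD+, CD4- T intensity 2x
higher in ESRD+ (higher still in ESRD-current), the CD4- archetype rate
2x higher in ESRD+, and mDC intensity reduced 4x in ESRD-current.
Absolute intensities (e.g. B at 2000 cells/mm^2 in ESRD-, total roughly
80 cells per HR field) were chosen once as plausible for inflamed
tubulointerstitium at these field sizes.  Marker flags in HMP mode are
drawn per cell from conditional probabilities matching the reported
compartment shares (Tfh ~36% of CD4+ T inside B-T clusters vs ~28%
elsewhere; Treg 2.5%; exhausted CD8 25%; TCRdelta+ 51.4% of DN cells).

`perturb_segmentation` degrades a ground-truth map into a synthetic
detector output — Bernoulli drops, Poisson spurious cells with masks
drawn from the true size distribution, Gaussian centroid jitter, disc
erosion/dilation, class flips, and confidence draws from separate
true/spurious ranges — giving detection evaluation a target with known
expected recall and precision.

What the generator does **not** emulate: fluorescence intensities,
autofluorescence, staining artifacts, segmentation-error correlations
with cell density, irregular tissue boundaries, patient-level covariates
(treatment, chronicity structure beyond a random score), and spatial
interaction between archetypes.  Passing tests therefore demonstrate
that the analysis recovers known planted structure at realistic scales,
not that it would behave identically on patient images.

## Scales used in tests

The test and acceptance runs use reduced problem sizes chosen to keep
the full suite fast while leaving comfortable statistical margins: ~1000
truth cells for detection calibration, 500 repeated experiments for
bootstrap CI coverage, 2000 neighborhoods for archetype recovery, the
full 55-biopsy default cohort (~850 ROIs, ~70k cells) for cohort-effect
recovery over 20 seeds, and nine 640x640 px sections per seed for the
periglomerular analysis (with the B-T parent rate raised to 80/mm^2 so
each run contains enough B-T aggregates to test).

## Known limitations

* Patient-level clustering is ignored by the ROI bootstrap (above).
* The 24-feature set is a reconstruction from the stated feature
  categories; the exact original list is not public.  The set and order
  are fixed and documented, and the archetype machinery does not depend
  on the specific choice.
* Cross-round matching for T-cell class combination uses the detection
  thresholds (IOU 0.25, 5 px centroid fallback); the original matching
  rule is unpublished.
* DBSCAN at min size 2 treats chains of cells ~10 um apart as one
  neighborhood regardless of total extent; this is inherent to the
  epsilon-graph definition.
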