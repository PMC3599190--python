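# Methods

This note documents the models and numerical choices behind
`lcmsalign`, what the synthetic-data generator does and does not
emulate, and the parameter defaults.

## Coordinates and units

All cross-run comparison happens in two dimensionless coordinates:

* **relative mass error** in ppm, Δppm = 10⁶·|m₁−m₂|/mean(m₁,m₂) for
  pair comparisons (for comparisons against a reference value r we use
  10⁶·(m−r)/r);
* **normalized elution time (NET)** in [0,1]: per run,
  net = (scan − scan_min)/(scan_max − scan_min) over the representative
  scans, which makes NET invariant to affine scan relabeling and
  comparable across runs of different length.

Distances normalize each axis by its tolerance, so 1.0 means "exactly
at tolerance"; this lets a single Euclidean distance mix mass and time.
Neutral mass and m/z are related by m/z = (M + z·p)/z with
p = 1.00727646688 Da (proton mass).

## Feature finding

MS features join an LC-MS feature only when within both hard gates
(mass_tolerance_ppm, default 10; scan_gap_tolerance, default 5 scans),
merging in ascending weighted-L2 distance order — which makes the final
grouping exactly the connected components of the gate graph, computed
by union-find over a mass-sorted window. The distance weights default
to (w_mass, w_time, w_intensity) = (1, 1, 0): intensity participates in
the distance only when enabled, because gating on intensity tends to
split saturated elution profiles at their plateau. Merge and
representative-scan ties break deterministically (smallest id pair,
smallest scan). `min_feature_length` defaults to 1 so single-scan
detections survive; raise it to suppress transient noise.

## Alignment (NET warp + mass recalibration)

Anchors are all (alignee feature, baseline entry) pairs within
`match_mass_tolerance_ppm` (default 10); the baseline is another run or
an AMT-tag database. Each anchor scores exp(−(Δppm/σ)²/2) with
σ = tolerance/2, so wrong-mass anchors contribute little. Scores
accumulate in a num_sections × num_sections (default 100×100) matrix
over (alignee NET section, baseline NET section) — the exported
heat-map data.

Dynamic programming then finds the maximum-score strictly monotone
chain of section cells with per-axis steps of 1..max_expansion_factor
(default 3), allowing the elution axis to stretch or compress locally
by up to that factor. Chain cells that contain anchors become warp
knots placed at the *Gaussian-weighted anchor centroid* of the cell
rather than the geometric cell center: with sparse anchors, cell
centers would bias the warp by up to half a section (0.005 NET at 100
sections), while anchor centroids sit on actual correspondences.
Evaluation linearly interpolates between knots and clamps flat outside
the knot range and to [0,1].

Mass recalibration is estimated separately: anchors are binned by
alignee NET into num_sections bins; the per-bin **median** Δppm (robust
to the false anchors that survive the mass gate) is linearly
interpolated into a ppm-shift curve; empty bins inherit the nearest
populated bin. Applying the alignment replaces each feature's NET by
the warp value and multiplies its mass by (1 − shift(net)·10⁻⁶);
pre-alignment values are retained.

Degenerate inputs: zero anchors raise an alignment error (rather than
silently returning identity); all anchors in one cell produce a
two-knot identity-slope warp; a run whose features share one scan gets
NET 0.5 everywhere with a warning.

## Cross-run clustering and scores

Features from all runs are sorted by calibrated mass and split at any
consecutive gap above mass_tolerance_ppm (default 10). No legal merge
can cross such a gap, so clustering each partition independently equals
clustering everything at once (asserted in the tests); partitioning
only bounds the quadratic work. Within a partition:

* **single linkage** (default): merge in ascending distance over
  gate-satisfying pairs (Δppm ≤ 10 ppm and ΔNET ≤ 0.03 by default) —
  again connected components of the gate graph;
* **average linkage**: iterative merging on centroid distance, with the
  gates applied to the centroid deltas, centroids recomputed after each
  merge.

Centroids are coordinate-wise medians (robust to a single outlier
member). Two members from the same run may share a cluster; the scores
expose such cases rather than a hard rule forbidding them.

Scores, both in normalized units so tolerances act as unit scales:

* **tightness** = mean member-to-centroid distance; exactly 0 for
  singletons; smaller = more coherent cluster.
* **ambiguity** = minimum member-pair distance to any *neighboring*
  cluster, where neighbors are clusters with centroids within 2× both
  tolerances — far enough to cover any cluster that could plausibly be
  confused, near enough to stay local. No neighbor ⇒ ambiguity = ∞
  (stored as SQLite Infinity). Ambiguity is scored globally after all
  partitions are clustered, because a neighbor can sit just across a
  partition boundary (boundaries only guarantee a 1× gap).

## Match confidence (mixture posterior) and uniqueness

Candidate (cluster, tag) matches come from a range query at the
matching tolerances (default 10 ppm, 0.03 NET). The match-error vectors
(Δppm, ΔNET) are modeled as a two-component mixture: true matches
follow N(μ_p, σ_p²)×N(μ_n, σ_n²); false matches are uniform over the
tolerance box. EM estimates (π, μ, σ), converging when the relative
log-likelihood change drops below 1e−8 (cap 500 iterations). Numerical
guards: σ is floored at 5% of its tolerance — a sharper peak is not
resolvable by the data and an unbounded normal would otherwise collapse
onto the tightest candidates (the classic degenerate-likelihood EM
solution) when nearly every candidate is a true match; π is clamped to
(1e−9, 1−1e−9). Below 20 candidates the fit is unreliable and a fixed
prior model (π = 0.5, zero means, σ = tolerance/2) is used with a
warning.

A match's confidence is the posterior of the true component; the
**uniqueness probability** renormalizes the confidences over each
cluster's competing matches (1.0 for a lone match; all-zero confidences
fall back to uniform with a warning). Uniqueness values sum to one per
cluster, so a cut at > 0.5 keeps at most one tag per cluster —
"unambiguously identified" is operationalized as uniqueness > 0.5.

## Spectral clustering and the delta-scan diagnostic

Only spectra linked to an LC-MS feature are clustered (linking: scan
within the feature span ± scan_window, default 10, and precursor m/z
within 0.05 Th of the feature's per-charge reconstructed m/z); a
spectrum with a supporting elution profile is unlikely to be transient
noise. Spectra are reduced to their 50 most intense peaks, intensities
square-rooted, binned at 1.0005 Th (the peptide mass-defect spacing)
and unit-normalized; similarity is the dot product — a cosine on
nonnegative unit vectors, hence in [0,1]. Clustering is greedy:
candidate pairs (precursor m/z within tolerance) merge in descending
similarity, and a merge stands only if every member keeps similarity ≥
similarity_threshold (default 0.7) to the merged cluster's
representative (highest total ion current). The representative-based
membership test is a deterministic, near-linear variant of hierarchical
clustering.

The delta-scan diagnostic lists, per spectral cluster, all scan
differences between member pairs drawn one from each of two named runs.
Technical replicates give residuals at zero; a systematic elution shift
appears as a shifted median; diverging samples appear as incoherent
spread.

## Synthetic data: what it emulates, what it does not

The generator plants analytes (mass, base NET, charge states,
per-run abundances, a fixed pseudo-random fragment template) and
renders per run: triangular elution profiles of 3–10 scans (the minimal
shape with a well-defined apex) on a 2000-scan range, one isos row per
charge per scan, mass jittered by N(0, sd_ppm) plus the run's
systematic offset (optionally drifting linearly across NET), scans
placed by the run's monotone piecewise-linear NET distortion (endpoints
pinned), per-run dropout, and MGF fragment spectra at scans inside the
profile. Masses are drawn on [500, 2500] Da with a minimum 0.05 Da gap
so planted analytes are resolvable at the default tolerances; fragment
templates are identical across runs (clusterable) and near-orthogonal
across analytes. A fixed seed yields byte-identical files.

Default noise levels are the study conditions of the recovery checks:
sd_ppm = 2 against the 10 ppm gates and sd_net = 0.005 against the 0.03
NET gate, five runs of 200 analytes, no dropout. The alignment-recovery
scenario uses a 3-segment distortion with 0.08 maximum displacement, a
+3 ppm drift, and post-calibration instrument-level noise (sd_ppm 0.5,
sd_net 0.002). The spectral contrast compares an idealized technical
replicate (zero noise, the limiting case of same-day reinjection)
against a +50-scan-shifted pair carrying cross-condition elution
variability (sd_net 0.002, chosen so the planted shift is identifiable:
the median's sampling error is ≈0.6 scans over ~100 clusters).

Not emulated: chimeric or overlapping isotope envelopes, abundance-
dependent mass error, gradient dead time and column re-equilibration
effects, background chemical noise, or missing-value structure beyond
Bernoulli dropout. Passing the recovery tests therefore shows the
algorithms are correct under the stated error model, not that real
instrument data will reach the same recall.

## Problem sizes

The test suite and the acceptance script run the full pipeline on
experiments of 100–200 analytes across 2–5 runs (≈1–10 thousand MS
feature rows per run) — large enough that partitioning, windowed
searches and the section DP are all exercised on non-trivial input,
small enough to re-run everywhere in seconds.

## Known limitations

* The warp DP cannot represent local stretch/compression beyond
  max_expansion_factor per section step; pathological gradients would
  need a larger factor or more sections.
* Average linkage recomputes centroid distances exactly (O(k³) within a
  partition); it is intended for the partition sizes mass-gapped data
  produces, not for one giant partition.
* The mixture model assumes independent Gaussian errors in mass and
  NET; correlated drift that survives alignment would miscalibrate the
  confidence somewhat (the uniqueness renormalization is unaffected).
* mzXML support is the minimal subset needed for traceback (scan,
  MS level, precursor m/z, peaks); vendor raw files must be converted
  upstream.
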