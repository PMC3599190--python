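# lcmsalign

Multi-dataset LC-MS feature alignment, cross-run clustering, AMT-tag
matching and MS/MS traceback for label-free comparative proteomics and
metabolomics.

## The problem

A label-free comparative experiment produces one deisotoped feature map
per LC-MS run: thousands of detections, each a monoisotopic mass *M*,
charge *z*, scan number and abundance. To compare conditions — or to
find analytes present everywhere but identified nowhere — the maps must
be put on a common scale and the *same analyte* recognized across runs,
despite run-to-run drift in elution time and small systematic mass
error. When a reference database of accurate-mass-and-time (AMT) tags
exists, features can then be identified without fresh MS/MS; when it
does not (environmental communities without a metagenome, metabolomes
without standards), interesting cross-run clusters can still be traced
back to the tandem spectra acquired on them and exported for downstream
identification.

`lcmsalign` implements that whole chain:

1. **Feature finding** — single-linkage grouping of MS features into
   LC-MS features under a weighted L2 distance
   d = sqrt(w_m (Δppm/τ_m)² + w_t (Δscan/τ_t)² + w_i Δlog₁₀I²),
   with hard join gates on the mass and scan axes; the representative
   scan is the elution-peak apex and abundance is the sum over members.
2. **Alignment** — each run's scan axis is min–max scaled to normalized
   elution time (NET ∈ [0,1]), then warped onto a baseline run or an
   AMT-tag database by a monotone piecewise-linear function found by
   dynamic programming over NET sections scored with mass-agreement
   anchors; a per-section median Δppm curve recalibrates the masses.
3. **Cross-run clustering** — gated single or average linkage over
   (mass, NET) inside mass partitions, with two quality scores per
   cluster: *tightness* (mean member-to-centroid distance) and
   *ambiguity* (closest member-pair distance to a neighboring cluster).
4. **Peak matching** — range query of cluster centroids against AMT
   tags; each match gets a posterior confidence from a two-component
   mixture (bivariate normal true matches vs uniform decoys, fitted by
   EM) and a per-cluster *uniqueness probability* that singles out the
   most likely tag.
5. **Spectral clustering** — feature-linked MS/MS spectra compared
   across runs by normalized dot product, with the per-cluster
   delta-scan residual diagnostic for elution reproducibility.
6. **Traceback** — SQL-joinable links from any cluster through its
   member features to the spectra that fragmented them, exportable as
   MGF.

A synthetic-data module generates complete experiments (isos CSVs, MGF
spectra, AMT-tag tables) from a planted ground truth, so every stage is
testable against known answers.

## Worked example

Generate a 3-run, 50-analyte synthetic experiment and analyze it:

```
$ lcmsalign generate --out demo --n-analytes 50 --n-datasets 3 --seed 7
wrote demo/manifest.yaml

$ lcmsalign run --manifest demo/manifest.yaml --out demo_results
done: 150 LC-MS features, 50 clusters, 50 tag matches -> demo_results/results.db3

$ lcmsalign summarize demo_results/results.db3
LC-MS features per dataset:
  ds00: 50
  ds01: 50
  ds02: 50
clusters: 50
non-singleton clusters: 50
clusters spanning all datasets: 50
unambiguous tag matches (uniqueness > 0.5): 50
```

Each of the 50 planted analytes is found in all three runs (150 LC-MS
features), clustered into exactly one cross-run cluster, and matched
unambiguously (uniqueness probability > 0.5) to its AMT tag. On real
data the interesting output is usually the opposite set — clusters
present across runs *without* an unambiguous match — which
`lcmsalign filter-clusters --unidentified` selects and
`lcmsalign export-spectra` dumps as MGF for identification tools.

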