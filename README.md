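# mzsift

Untargeted LC-HRMS metabolomics for in vitro drug-metabolite discovery.

When a new psychoactive substance (for instance a synthetic cathinone) is
incubated with pooled human liver microsomes (pHLM), the CYP-formed
metabolites are conventionally identified by an expert reading MS/MS
spectra. An untargeted metabolomics workflow replaces that first,
experience-bound step with statistics: incubate at three substrate levels
(Blank = 0, Low, High), acquire full-scan LC-HRMS data, detect
chromatographic features, and let group comparisons reveal every ion whose
abundance tracks the dose — metabolites, but also isotopologues, adducts,
in-source artifacts and powder impurities, which mass-shift logic then
separates from the true biotransformation products.

`mzsift` re-implements that workflow end to end as a tested, reusable
library and CLI:

- **`mzsift.chem`** — elemental-formula arithmetic, monoisotopic masses,
  ion m/z for species like [M+H]⁺, [M−H]⁻, [2M+2H+Cl]⁺, the
  biotransformation catalogue (dihydro- +H₂, HO- +O, oxo- +O−H₂,
  N,N-dealkyl- −C₄H₆, …), and "M218T216"-style feature naming.
- **`mzsift.simulate`** — a synthetic-data generator that emulates the
  incubation study design (3 groups × 5 replicates, pooled QC injected 5×
  then every 5th injection, substrate- and enzyme-blank duplicates) with a
  ground-truth ledger for every planted species.
- **`mzsift.peaks`** — ROI tracing over centroided scans, Gaussian-smoothed
  peak detection, single-linkage feature grouping, and gap-filling that
  reintegrates consensus RT windows (deliberately integrating noise in
  blanks, as real reintegration does).
- **`mzsift.stats`** — signed fold changes, Welch's two-sample t-test, and
  the significance filter: |FC| > 1.5 with p < 0.001 in the same group
  comparison, RT within [60, 600] s; then zero→surrogate-LOD replacement
  and log₁₀ transform.
- **`mzsift.drift`** — QC-anchored injection-order drift correction: per
  feature detected in every QC, a linear model of log₁₀ abundance vs
  injection index, extrapolated to all samples.
- **`mzsift.mva`** — PCA (full-rank, deterministic signs), t-SNE, and
  hierarchical clustering with per-feature z-scores.
- **`mzsift.annotate`** — classification of significant features as
  isotopes (+k × 1.003355, co-eluting, less abundant), adducts,
  in-source artifacts (mass-shift match co-eluting with the parent),
  impurities (present in the enzyme blank, absent from the substrate
  blank), or metabolites (dose-responsive, absent from both blanks), with
  isomer/conformer cross-linking by retention time.
- **`mzsift.io` / `mzsift` CLI** — a columnar text format for centroided
  runs, centroided-mzML reading, YAML configuration, and pipeline
  orchestration with an auditable manifest.

## Worked example

```python
from mzsift.io import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig(seed=1))
print(len(result.table_raw.feature_names))        # 713
print(len(result.filtered_raw.feature_names))     # 31
print(round(result.pca.variance_explained[0], 2)) # 98.82
print(result.annotation_df["class"].value_counts().to_dict())
# {'isotope': 18, 'metabolite': 8, 'parent': 2, 'impurity': 1,
#  'artifact': 1, 'adduct': 1}
```

Reading: peak detection over the 27 simulated injections found 713
features; 31 survive the fold-change/p-value/RT filter; 98.82% of the
variance of the processed table sits on the first principal component —
the collinearity expected when the parent compound dominates every
mixture and all significant features track it. The annotation table
(`result.annotation_df`) mirrors a published significant-feature list:

```text
 feature        mz   rt_s  identity
M216T114  216.1383    114  impurity (dehydro-)
M216T216  216.1383    216  artifact (dehydro-)
M218T216_2 218.1539   216  parent ([M+H]+) isomer 1
M219T216  219.1573    216  isotope 13C-isotope
M220T226  220.1696    226  metabolite (dihydro-) isomer 1
...
```

The dehydro-shifted ion at the parent's retention time is called an
in-source artifact; the same mass shift eluting elsewhere and present in
the enzyme blank (substrate without microsomes) is an impurity of the drug
powder; the dose-responsive dihydro/oxo/HO-shifted features are
metabolites. The same pipeline is available from the shell:

```sh
mzsift run-all --seed 1 --out-dir out
# 31 significant features; PC1 98.8%; outputs in out
mzsift report --out-dir out
```

Each stage is also a separate subcommand (`simulate`, `pick`, `stats`,
`correct`, `mva`) operating on the documented text formats.

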