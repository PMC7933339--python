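# mwfp — multi-wavelength HPLC fingerprint fusion for origin discrimination

`mwfp` implements a complete chemometric workflow for telling apart the
geographical origins of a herbal raw material — here *Panax notoginseng*
(Sanqi) roots from Sichuan versus Yunnan province — from HPLC-DAD
fingerprints.  The legal quality markers (individual saponin contents)
do not separate the two origins; the workflow shows that a **fused
fingerprint**, obtained by projecting the chromatograms recorded at
203 nm, 270 nm and 325 nm along the wavelength axis (a point-wise sum of
the traces), discriminates the origins better than any single-wavelength
fingerprint, because saponins, flavonoids and amino acids absorb in
different bands and each carries part of the origin signal.

The package is aimed at analytical chemists and chemometricians working
on quality control of herbal materials, and at anyone who needs an
auditable, scriptable reference implementation of quantified-fingerprint
similarity grading.

## What is implemented

* **Peak processing** — rolling-minimum baseline correction,
  prominence-based peak detection with valley-to-valley trapezoidal
  integration, and greedy retention-time matching across samples into a
  *co-possessing peak* matrix (peaks present in every sample).
* **MWFP fusion** — point-wise summation of a sample's single-wavelength
  traces before peak detection; linear, channel-order invariant, and
  area-conserving.
* **ALQFM similarity grading** — each sample's peak-area vector *x* is
  scored against a reference fingerprint *y* with ratios
  *r\_i = x\_i / y\_i* over the *n* shared peaks:

  * qualitative similarity
    *Sm = (S\_cos + S\_prof) / 2*, with
    *S\_cos = x·y / (‖x‖‖y‖)* and
    *S\_prof = Σᵢ min(pᵢ, qᵢ)* for the area fractions *p = x/Σx*,
    *q = y/Σy*;
  * quantitative similarity *Pm = 100 · mean(r)* (percent);
  * variation coefficient *α = sd(r)/mean(r)* (n−1 denominator).

  The three are combined into an eight-level **grade** (1 best … 8
  worst) via a nested threshold table, taking the worst of the three
  component ratings; grade ≤ 5 conventionally means "similar to the
  reference".
* **Chemometrics** — hierarchical clustering (between-groups/average
  linkage on squared Euclidean distances), PCA, and two-class OPLS-DA
  with VIP scores, all implemented in-repo; PCA and OPLS-DA follow the
  scikit-learn estimator protocol.
* **Quantitation** — linear calibration (R², 3.3·σ/slope LOD),
  solution-to-content conversion (0.500 g / 20 mL extraction → ×40),
  per-compound mean and RSD%, Welch two-sample t-tests between origins.
* **Synthetic studies** — a generator producing complete 32-batch,
  three-wavelength studies with known ground truth (Gaussian peaks,
  noise, baseline drift, origin-dependent contents), so the whole
  pipeline is testable end to end without instrument data.
* **Bundled reference tables** — the published per-batch saponin
  contents and ALQFM similarity report of the real 32-batch study.

## Worked example

Run the full pipeline on the default synthetic study (15 + 17 samples,
33 compounds, 15 of them carrying an origin effect):

```sh
mwfp run --seed 2
```

The tail of the output:

```
203: 11 discrimination errors (cutoff 4, similar group Yunnan)
270: 0 discrimination errors (cutoff 4, similar group Yunnan)
325: 1 discrimination errors (cutoff 4, similar group Yunnan)
fused: 0 discrimination errors (cutoff 4, similar group Yunnan)
HCA (k=2) misassignments: 0
OPLS-DA R2Y: 0.969
peaks with VIP > 1: 15
```

Reading: grading each sample against a designated benchmark batch and
calling grade ≤ 4 "same origin as the benchmark" misclassifies 11 of 32
samples at 203 nm but none on the fused fingerprint — the fusion
advantage; 2-cluster HCA of the fused peak matrix recovers the two
origin groups without error; OPLS-DA explains 97% of the class variable
and its VIP > 1 set flags exactly the 15 compounds the generator
injected with an origin effect.

The same analysis from Python:

```python
import mwfp

cfg = mwfp.PipelineConfig(synthetic=mwfp.SyntheticStudyConfig(seed=2))
report = mwfp.run(cfg)
report.alqfm_wide          # per-sample Sm/Pm/alpha/grade, 4 channels
report.discrimination      # per-channel confusion counts
report.vip                 # per-peak VIP with the VIP > 1 flags
```

Grading a single sample by hand:

```python
>>> mwfp.assign_grade(sm=0.883, pm=94.3, alpha=0.047)
3
```

## Layout

| module | contents |
| --- | --- |
| `mwfp.io` | chromatogram/manifest text formats, validation |
| `mwfp.peaks` | baseline, detection, integration, matching |
| `mwfp.fusion` | wavelength fusion, fingerprint-matrix construction |
| `mwfp.alqfm` | Sm/Pm/α, grade criteria, grading, discrimination counts |
| `mwfp.chemometrics` | HCA, PCA, OPLS-DA, VIP |
| `mwfp.quantitation` | calibration, contents, summary stats, t-tests |
| `mwfp.simulate` | synthetic-study generator and ground truth |
| `mwfp.datasets` | bundled published tables |
| `mwfp.pipeline`, `mwfp.cli` | orchestration and the `mwfp` command |

See `docs/methods.md` for the underlying models, parameter choices and
limitations.
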