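# dbsdiff

Quantifying what survives of a diffusion-MRI analysis after deep-brain-
stimulation (DBS) surgery.  Post-operative diffusion scans of implanted
patients are degraded in three distinct ways — an order-of-magnitude SNR
drop (1.5 T awake scan vs 3 T anesthetized), head motion, and susceptibility
signal dropout around the electrode and its connection wire — and each of
these biases the standard DTI/tractography outputs differently.  `dbsdiff`
implements the complete within-subject pre/post comparison workflow and a
synthetic two-session phantom generator that emulates exactly those three
degradations with known ground truth, so every stage is testable without any
patient data.

The package is for imaging methodologists and pipeline engineers who need a
verifiable, desk-scale implementation of:

* **DTI scalars** — weighted log-linear tensor fit; FA, MD, RD from the
  eigenvalues λ₁ ≥ λ₂ ≥ λ₃:
  `FA = √(3/2)·‖λ − λ̄‖/‖λ‖`, `MD = (λ₁+λ₂+λ₃)/3`, `RD = (λ₂+λ₃)/2`.
* **Quality metrics** — `SNR = Mean_GM / SD_AIR`,
  `CNR = (Mean_GM − Mean_WM) / SD_AIR`, averaged across volumes.
* **Motion correction** — per-volume rigid registration to the b0 image
  with b-vector reorientation, and pre/post motion summaries.
* **Artifact-aware ROI statistics** — ROIs intersecting the dropout mask
  are "affected"; each (ROI, scalar) pair runs a Kolmogorov–Smirnov gate
  that routes to a paired Wilcoxon signed-rank test (distributions differ)
  or a paired t-test with 95% CI (distributions similar).
* **Bayesian crossing-fiber tractography** — a ball-and-stick posterior
  (≤2 sticks per voxel, MCMC with automatic-relevance priors) feeding a
  probabilistic streamline tracker (bidirectional, 0.5 mm steps, curvature
  threshold 0.2 as a minimum step cosine, loopcheck, classification
  targets).
* **Tract-retention statistics** — the *index of connection probability*
  (mean successful samples per seed voxel), the *streamline density*
  (percent of seed voxels with ≥1 successful streamline), their percent
  change `100·(pre − post)/pre`, and a voxel-wise Welch t-test of the
  connection maps inside each target ROI.

## Worked example

Run the reduced desk-scale study (24³ phantom at 2 mm, 32 directions at
b = 800 s/mm², three tracts, 100 tracking samples per seed voxel):

```python
import dbsdiff as dd

result = dd.run_study(dd.StudyConfig.fast(master_seed=7))
print(result.connectivity.to_string(index=False))
```

which prints (abridged):

```
               tract  index_pre  index_post  index_percent_change  density_pre  density_post  density_percent_change  welch_p  similar
       nigrostriatal      100.0      96.500                   3.5        100.0         100.0                     0.0    0.933     True
dentatorubrothalamic      100.0       0.000                 100.0        100.0           0.0                   100.0    0.002    False
         hyperdirect      100.0      83.821                  16.2        100.0         100.0                     0.0    0.689     True
```

Reading the table: the pre-operative session reconstructs all three tracts
perfectly (index = samples-per-voxel, density 100%).  The post-operative
session carries 8× more noise, per-volume motion, and a signal-dropout
sphere that bisects the dentato-rubro-thalamic bundle — that tract collapses
completely (100% loss, Welch p = 0.002: pre and post connection maps
differ), while the two tracts that merely suffer the noise lose only a few
percent of their connection index and stay "similar" (p > 0.05).  The same
run reports session SNR 153.2 (pre) vs 19.0 (post) and finds 100% of ROIs
with KS-different FA distributions — the FA inflation expected from Rician
noise at low SNR.

The equivalent shell command is `dbsdiff run-study --out out/ --seed 7
--fast`; `dbsdiff generate`, `preprocess`, `fit`, `quality`, `roistats`,
`track` and `connectivity` expose the individual stages on NIfTI/bval-bvec
session directories.

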