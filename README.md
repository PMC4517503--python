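# lvconsensus

Multi-reader consensus contours and agreement analysis for left-ventricular
(LV) function from short-axis cardiac MR.

When several expert readers contour the same cine CMR study, their
endocardial and epicardial contours differ systematically: each reading
centre's protocol places contours consistently tighter or wider, so LV
volumes and mass carry reader-specific bias even though each reader is
internally precise.  `lvconsensus` is a contour-only pipeline for
quantifying that variability and for building an unbiased reference:

- **STAPLE consensus contours.**  Per slice and surface, reader contours
  are rasterized to binary decision maps `D_ij` at 4x the pixel grid and
  fused by Simultaneous Truth and Performance Level Estimation: an EM
  algorithm that estimates the consensus probability map `W` together with
  each reader's sensitivity `p_j` and specificity `q_j`,

  ```
  E-step:  W_i = a_i / (a_i + b_i)
           a_i = π · Π_j p_j^{D_ij} (1 − p_j)^{1−D_ij}
           b_i = (1 − π) · Π_j (1 − q_j)^{D_ij} q_j^{1−D_ij}
  M-step:  p_j = Σ_i W_i D_ij / Σ_i W_i
           q_j = Σ_i (1 − W_i)(1 − D_ij) / Σ_i (1 − W_i)
  ```

  initialized from the pixel-voting map, restricted to a region of
  interest around the reader masks, iterated to convergence.  A consensus
  contour is extracted at `W ≥ 0.5` only where four or more readers
  contoured the slice.

- **Slice-summation volumetrics.**  EDV and ESV as Σ (cavity area ×
  inter-slice distance); LV mass as (epicardial volume − EDV) × 1.05 g/ml
  at ED; EF = 100 (EDV − ESV)/EDV; ES frame selection by smallest
  mid-ventricular cavity area.

- **Agreement statistics.**  Inter-reader RMSE
  `E_i(F) = sqrt( Σ_{j≠i} Σ_k (F_i(k) − F_j(k))² / (N(R−1)) )`,
  consensus RMSE
  `E_C(F) = sqrt( Σ_j Σ_k (F_C(k) − F_j(k))² / (NR) )`,
  per-reader Bland-Altman bias/precision/limits of agreement against the
  consensus, and per-case consensus ± standard error.

- **Reader reports.**  Per-slice point-to-consensus distances with > 3 mm
  flags, cross-reader range bands, and mean/max/SD summaries, as data
  (CSV) plus a rendered figure.

- **Synthetic cohorts.**  A truncated-ellipsoid LV phantom generator and a
  simulated reader panel (per-reader systematic radial bias, smooth
  angular noise, occasional missing end slices) so the full pipeline can
  be exercised and validated without clinical data.

## Worked example

```python
from lvconsensus import CohortConfig, run_cohort_analysis

analysis = run_cohort_analysis(CohortConfig(seed=1))
for name, rep in analysis.reports.items():
    print(f"{name:>3}: E_C = {rep.e_c:5.2f}   "
          f"E_i in [{rep.e_i.min():5.2f}, {rep.e_i.max():5.2f}]   "
          f"bias in [{rep.bias.min():6.2f}, {rep.bias.max():6.2f}]   "
          f"consensus best: {rep.consensus_is_best}")
case = analysis.reports["EDV"]
print(f"case01 consensus EDV = {case.per_case_consensus[0]:.1f}"
      f" +/- {case.per_case_se[0]:.1f} ml")
```

prints

```
EDV: E_C = 16.54   E_i in [18.06, 33.83]   bias in [-22.12,  26.19]   consensus best: True
ESV: E_C = 12.93   E_i in [14.03, 25.72]   bias in [-17.72,  18.39]   consensus best: True
LVM: E_C = 32.66   E_i in [35.31, 69.13]   bias in [-51.32,  55.10]   consensus best: True
 EF: E_C =  1.99   E_i in [ 2.16,  3.73]   bias in [ -1.70,   2.96]   consensus best: True
case01 consensus EDV = 151.5 +/- 5.1 ml
```

This simulates a 15-case, 7-reader cohort with zero-mean reader biases,
fuses every slice with STAPLE, computes EDV/ESV/LVM/EF for every reader
and for the consensus, and reports the agreement statistics.  The
consensus RMSE (`E_C`) is below every individual reader's RMSE (`E_i`)
for all four indices: the consensus agrees with the reader panel better
than any single reader does, while the per-reader biases (tens of ml in
volume, tens of g in mass) reflect the systematic protocol differences
the simulation encodes.

The same pipeline is available from a shell:

```
lvconsensus simulate --out cohort --seed 1
lvconsensus consensus --in cohort --out consensus
lvconsensus analyze --in cohort --consensus-dir consensus --out analysis --reports
```

All inputs and outputs use a plain-text contour exchange format (one CSV
record per contour point) documented in `lvconsensus.contour_model`.

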