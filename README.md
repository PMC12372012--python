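# fuzzedge

Fuzzy and ant-colony edge analysis for 2-D medical images.

Medical images — MRI brain slices in particular — have soft, uncertain
boundaries: partial-volume effects, noise and anatomical ambiguity make hard
binary edge decisions unreliable. `fuzzedge` is a scriptable library and CLI
for analysing such images with methods that keep the uncertainty explicit:

* **classical edge detection** (Prewitt, Sobel, Roberts, Canny) and
  enhancement filters (Laplace, Sobel gradient, smoothed Sobel gradient,
  sharpen);
* **ant colony optimization (ACO) edge extraction** with four pluggable
  heuristic kernels (`kh`, `chi`, `sin`, `pow`): artificial ants step
  between 8-neighbors with probability ∝ τ^α·η^β (pheromone τ, local
  intensity variation η) and concentrate pheromone on discontinuities;
* **fuzzy edge maps** (S-function membership of the smoothed gradient) and
  **fuzzy edge linking** (hysteresis plus gap bridging);
* **fuzzy C-means clustering** of intensities into k soft tissue classes,
  minimising J = Σ_p Σ_k u_pk^m (x_p − v_k)²;
* an **uncertainty-aware evaluation layer**: for a reference fuzzy set Ni
  and a detected set Nd over an m×n grid,

  ```
  FTP = min(Ni, Nd)    FFP = max(0, Ni − Nd)    FFN = max(0, Nd − Ni)

            |FTP| · Σ_ij 1/(1 + FD(i,j)) − |FFP| − |FFN|
  FI  =  ──────────────────────────────────────────────────
                    m · n · max(|Ni|, |Nd|)
  ```

  where |X| is the scalar cardinality (grid sum) and FD is the distance to
  the nearest detected pixel normalized by maxD = √((m−1)² + (n−1)²) — a
  Pratt-figure-of-merit style weighting;
* **alpha-cut statistics**: a metric observed over several methods is
  summarized by mean, sample std/variance, the nested intervals
  mean ± std·√(1−α), and a Student-t confidence interval.

A synthetic phantom module (step, disk and nested-tissue images with
analytically known edges and labels) makes every stage testable without any
image downloads.

## Worked example

Evaluate the four ACO operators of the shipped MRI benchmark (first case
study, Canny reference) with the statistics layer:

```python
import fuzzedge as fz

tab = fz.benchmark_table()
cs1 = tab[tab.case == "CS1"]

s = fz.describe_values(cs1.fi)
print(round(s.mean, 4), round(s.sample_std, 4), round(s.sample_variance, 4))
# 0.8669 0.0514 0.0026

for a, lo, hi in fz.alpha_cut_intervals(fz.describe_values(cs1.pct_ftp)).rows:
    print(f"alpha={a:.2f}  [{lo:.2f}, {hi:.2f}]")
# alpha=0.00  [13399.24, 15071.98]
# alpha=0.25  [13511.29, 14959.92]
# alpha=0.50  [13644.21, 14827.01]
# alpha=0.75  [13817.42, 14653.79]
# alpha=1.00  [14235.61, 14235.61]

print([round(x, 2) for x in fz.t_confidence_interval(cs1.pct_ftp, 0.95)])
# [12904.76, 15566.46]
```

The mean fuzzy index 0.8669 ± 0.0514 says the four operators agree well
with the Canny reference on average, while the wide α = 0 cut of %FTP
(±836 around 14 235.61) reflects the one operator (`pow`) that detects a
sparser, more selective edge set than the other three.

End-to-end on a synthetic phantom from the shell:

```sh
fuzzedge synth --kind disk --side 64 --out-dir work/
fuzzedge edges work/disk.png --method canny   --out work/canny.png
fuzzedge edges work/disk.png --method aco_pow --iterations 100 --stages 1 \
         --seed 7 --out work/aco.png
fuzzedge metrics --reference work/canny.png --detected work/aco.png \
         --out work/metrics.csv
```

`metrics.csv` contains the fuzzy cardinalities, percent summaries and the
fuzzy index of the ACO detection against the Canny reference; `fuzzedge
stats` turns a table of such rows into the mean/std/alpha-cut summary above.

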