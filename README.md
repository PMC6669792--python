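# ybalance

Nonlinear movement-complexity analysis for dynamic balance testing.

During a Y Balance Test — a single-leg stance with maximal reaches of the
free leg — postural control shows up not in mean joint angles but in the
*dynamics* of the recorded signals: ankle and knee joint angles, the
center of pressure (CoP) on the force plate, and surface EMG of the
stabilizing muscles. `ybalance` quantifies those dynamics with two
complexity measures that work on short, non-stationary series and
compares them across experimental conditions (e.g. no tape / strapping
tape / kinesiology tape applied to the ankle) in a repeated-measures
design. It is aimed at movement scientists and biomechanists who have
long-format trial recordings — or who want a fully synthetic study with
known ground truth to validate an analysis chain end to end.

## The measures

**Higuchi fractal dimension (HDf).** For a series $x(1),\dots,x(N)$ and
time interval $k$, the normalized curve length at offset $m$ is

$$L(m,k)=\frac{1}{k}\left[\sum_{i=1}^{\lfloor (N-m)/k\rfloor}|x(m+ik)-x(m+(i-1)k)|\right]\frac{N-1}{\lfloor (N-m)/k\rfloor\,k},$$

$L(k)$ averages $L(m,k)$ over the $k$ offsets, and HDf is the slope of
$\ln L(k)$ against $\ln(1/k)$ for $k=1..k_{\max}$ (default $k_{\max}=8$).
A smooth trend gives HDf $=1$; white noise gives HDf $\approx 2$; a
fractional Brownian motion path with Hurst exponent $H$ has theoretical
fractal dimension $2-H$, which is the package's built-in ground truth.

**SVD entropy (SvdEn).** The series is delay-embedded (dimension $m=2$,
delay $\tau=1$ by default), the singular values $\sigma_i$ of the
embedding matrix are normalized to $\bar\sigma_i=\sigma_i/\sum_j\sigma_j$,
and

$$H_{\mathrm{SVD}}=-\sum_{i=1}^{M}\bar\sigma_i\log_2\bar\sigma_i \in [0,\log_2 m].$$

SvdEn is read as the number of independent attributes needed to describe
the signal: rank-1 dynamics give exactly 0, an i.i.d. series gives
$\approx 1$ bit at $m=2$.

Per trial, both measures are computed on the same conditioned series:
joint angles are low-passed (Butterworth, 4th order, 18 Hz), CoP at
50 Hz, EMG is band-passed 20–450 Hz, rectified and smoothed into a
linear envelope, and every channel is resampled to exactly 1001 frames.
Per-subject values are the mean of five trials; conditions are compared
with a repeated-measures ANOVA and Tukey post-hoc tests.

## Worked example

```python
from ybalance import BalanceComplexityModel, SyntheticStudySpec

spec = SyntheticStudySpec(n_subjects=10, n_trials=5,
                          channels=("ankle_AP", "ankle_ML", "ankle_SI"),
                          seed=42)
results = BalanceComplexityModel.from_synthetic(spec).fit()
print(results.summary())
```

```
Movement-complexity condition comparison
========================================
subjects (complete cases): 10    ANOVA mode: within_subject

SVD entropy (bits)
------------------
channel                           NT                ST                KT        F        p
ankle_AP            0.002031 ±0.00011  0.000803 ±3.9e-05 0.0009212 ±8.5e-05     62.5 7.97e-09
ankle_ML              0.1016 ±0.0078    0.1885 ± 0.011     0.173 ±0.0093     24.6 7.13e-06
ankle_SI              0.0296 ±0.0015   0.01206 ±0.0007   0.01207 ±0.00063      151 5.51e-12

Higuchi fractal dimension
-------------------------
channel                           NT                ST                KT        F        p
ankle_AP               1.209 ±0.0075     1.203 ±  0.01     1.197 ± 0.014    0.515    0.606
ankle_ML                1.26 ±0.0041      1.35 ±0.0047     1.351 ±0.0046      669 1.28e-17
ankle_SI               1.341 ± 0.005     1.289 ±0.0031     1.292 ±0.0043     82.4 8.68e-10
```

The synthetic study injects two taping effects at the ankle, and the fit
recovers both: SvdEn drops under tape in the sagittal (AP) and
transverse (SI) planes (fewer latent sources, stronger DC dominance),
while HDf rises mediolaterally (the sway path is generated with a lower
Hurst exponent under tape, i.e. a rougher trajectory). Knee, CoP and
EMG channels carry no injected effect and stay non-significant.
`results.comparisons` holds the per-channel ANOVA and Tukey-adjusted
pairwise p-values; `results.to_tables(outdir)` writes one CSV per
measure and channel family (six tables for the full channel set).

The same chain is scriptable from a shell:

```sh
ybalance simulate --seed 1 --out study/       # long CSV + ground truth
ybalance analyze study/ --out results/        # six comparison tables
ybalance validate                             # quick estimator self-checks
```

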