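# polaridar

Estimating flying-insect signal diversity from polarimetric lidar.

Entomological lidar records thousands of insect transits per day as
co-polarized and de-polarized backscatter waveforms sampled at 2 kHz along a
~500 m transect. Each transit carries a wingbeat-frequency (WBF) fundamental
and harmonic overtones; glossy wings produce brief specular flashes that
preserve polarization, diffuse wings de-polarize. This package implements
the full analysis chain for such data, with a synthetic-data generator that
emulates the statistical structure of a field recording so every stage is
testable against known ground truth:

1. **Extraction** — per range pixel, samples of the summed intensity above
   the median + 5×IQR of a 5-second file become event candidates; transits
   not exceeding 40 ms (the reciprocal of the 25 Hz minimum observable WBF)
   are discarded.
2. **Spectra** — Welch power spectral densities per channel (80-sample
   segments, Gaussian window with FWHM of half a segment, 79-sample overlap)
   on 80 linear bins over 25–1000 Hz, and three dataset modes:
   unpolarized `(P_co+P_de)/Σ(P_co+P_de)`, co-polarized `P_co/ΣP_co`, and
   DoLP `P_co/Σ(P_co+P_de)`, whose area is the observation's degree of
   linear polarization (co-fraction convention: 0.5 = randomized).
3. **Clustering, two routes** — Ward hierarchical clustering with the
   cluster count chosen from compensated linkages
   `L*_i = (i/N)^(−γ) L_i` (γ = median log-log slope of the reverse-ordered
   merge heights; outliers above Q3 + 1.5·IQR count the clusters); and a 3-D
   UMAP embedding followed by full-covariance Gaussian mixtures selected by
   `BIC = ln(n)k − 2ln L`.
4. **Diversity and structure** — Hill numbers
   (H0 = S, H1 = exp(−Σp ln p), H2 = 1/Σp²), ranked abundance
   distributions, adjusted mutual information and homogeneity between
   routes, bootstrap mean-DoLP confidence intervals against random-cluster
   nulls with quartile groups Q1 (glossy) to Q4 (diffuse), and time/range
   communities from two-sample Kolmogorov–Smirnov p-value similarity
   matrices via modularity maximization.

See `docs/methods.md` for the model details, parameter defaults and known
limitations.

## Worked example

The numbered scripts under `analysis/` run the chain on a synthetic field
day and write their tables under `results/`:

```
python analysis/01_simulate.py --seed 1     # species library + transits
python analysis/02_extract.py  --seed 1     # streams -> threshold extraction
python analysis/03_spectra.py               # Welch spectra, three modes
python analysis/04_cluster.py  --seed 1     # both clustering routes
python analysis/05_diversity.py             # Hill numbers + agreement
python analysis/06_communities.py --seed 1  # K-S communities + DoLP quartiles
python analysis/07_validation.py --seed 1   # recovery on controlled ensembles
```

With seed 1 this prints, among other things:

```
simulated 2000 transits; 16.0% below the 40 ms detection limit
injected 2000, matched 1641 (82.0%); 0 unmatched detections
observation DoLP: median 0.461, range 0.040-0.961
unpol: hierarchy selected k=1 (gamma=-1.353); mixture BIC selected k=40 (AIC would pick 40)
...
method  mode  axis  n_communities  modularity
   gmm  dolp  time            3.0      0.1941
   gmm  dolp range            2.0      0.1494
...
k within [G-1, G+2]: hierarchy 100%, mixture 87%; median AMI vs truth 0.97 / 0.97
```

Reading the numbers: the transit filter removes the expected ~16–18 % of
simulated transits and extraction recovers 82 % of them with no false
detections; per-observation DoLP spans the glossy-to-diffuse range the
library was built with. On this field-like data the mixture route partitions
the observations into ~40 clusters (the top of the desk-scale scan grid)
with positive time/range community structure (M ≈ 0.15–0.19), while the
compensated-linkage rule selects a single cluster: under the full 25 %
within-species WBF band and natural transit variation, merge heights form an
unbroken power law with no outlying merges — the rule finds significant
structure only when species form compact, well-separated spectral clouds, as
the controlled ensembles of `07_validation.py` show (selected k within
[G−1, G+2] and AMI ≈ 0.97 against the true species labels for
G = 3, 6, 12). `docs/methods.md` discusses this regime dependence.

All computation lives in the library (`src/polaridar/`); the scripts are
thin drivers, so the same results are available programmatically:

```python
from polaridar.pipeline import RunConfig, run
results = run(RunConfig(master_seed=1, n_obs=500, out_dir="results/demo"))
print(results["hill_table"])
```

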