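# elf-expochar

Stochastic characterization of personal exposure to extremely-low-frequency
magnetic fields (ELF-MF, measured in µT by a wearable dosimeter). Personal
24-h recordings are typically piecewise stationary — abrupt changes in mean
level and dispersion as the wearer moves between environments — so the
package:

1. **segments** each 00:00–24:00 day into stationary events with PELT under
   a penalized Gaussian AR(1) likelihood, describing every event by
   p = (μ, σ², φ, T) — mean level, dispersion, variation speed, duration;
2. **estimates** product-Gaussian kernel densities of the four parameters
   per subgroup (day/night window, age group, town size, distance to the
   nearest MV/LV substation), with below-resolution dispersions reported as
   a point mass instead of being smoothed;
3. **compares** subgroups with the energy (Cramér) two-sample test inside a
   Monte-Carlo subsampling scheme (m events per pool, repeated), summarized
   as a p-value histogram with Storey's false-discovery-rate estimate.

Within a segment, y_t = μ + φ(y_{t−1} − μ) + σz_t with iid standard-normal
z_t; segmentation minimizes Σ segment costs + β·k with the conditional
Gaussian likelihood cost and β = 3·log n by default. The energy statistic
between samples X (n_x × 4) and Y (n_y × 4) is
T = n_x n_y/(n_x+n_y) [ mean‖x−y‖ − ½ mean‖x−x′‖ − ½ mean‖y−y′‖ ], with
significance by permutation.

Because the measurement campaigns this methodology targets are not public,
a first-class synthetic-data module generates exposure days with known
ground truth (piecewise AR(1) segments, day/night contrast, the 0.01–300 µT
sensor window), and everything is validated against it. See
`docs/methods.md` for the full model, parameter defaults, and limitations.

## Worked example

The `analysis/` scripts run the whole chain on a synthetic cohort, writing
tables under `results/`:

```sh
python analysis/01_simulate_cohort.py     # 20 subjects, 24-h days at 30 s
python analysis/02_segment_events.py      # PELT -> labeled events table
python analysis/03_estimate_densities.py  # day/night KDEs of (mu, s2, phi, T)
python analysis/04_compare_subgroups.py   # subsampled energy tests + FDR
```

Output from one run (seed 0):

```
19 full days -> 203 events (10.7 per day) -> results/events.csv
day: 127 segments, night: 76 segments
day   (n=127): mu peak 0.0133 µT, sigma2 peak 1.76e-06 µT² (+2.4% point mass), phi peak 0.44, T peak 4243 s
night (n=76): mu peak 0.0116 µT, sigma2 peak 1.66e-07 µT² (+0.0% point mass), phi peak 0.48, T peak 3300 s
daynight: day (n=127) vs night (n=76): frac(p<0.05)=1.00, FDR=0 -> different
age: 0-4 (n=27) vs 10-14 (n=63): frac(p<0.05)=0.01, FDR=1 -> similar
```

Reading: one simulated day shy of 24 h was dropped by the full-day rule;
segmentation found ~11 events per day. Day events sit at higher mean levels
than night events (KDE peaks 0.0133 vs 0.0116 µT) and a small share of day
dispersions fall below numerical resolution (the 2.4% point mass —
sensor-saturated constant stretches). The day-vs-night p-value histogram
piles up below 0.05 (fraction 1.00, FDR ≈ 0): the two windows do not share
a distribution. Age groups carry no built-in effect in this cohort, and the
0–4 vs 10–14 comparison is correspondingly uniform (fraction 0.01, FDR 1);
with very small pools the subsample equals the pool and the driver prints a
degeneracy note.

The same pipeline is scriptable from one YAML config
(`analysis/configs/run_daynight.yaml`) through the CLI:

```sh
elf-expochar run --config analysis/configs/run_daynight.yaml
elf-expochar simulate --subjects 10 --seed 3 --out results/fx
elf-expochar segment --in results/fx --out results/events.csv --penalty auto
elf-expochar compare --events results/events.csv --split daynight --m 100 --reps 300
```

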