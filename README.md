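# lamindyn

A-type lamins form stable filaments at the nuclear periphery, but a smaller,
mobile pool of lamin A/C lives in the nuclear interior, where its binding
partner LAP2α keeps it in a low-assembly, diffusible state. `lamindyn`
implements the quantitative machinery needed to study that nucleoplasmic
pool: image-based nucleoplasmic-to-peripheral (N/P) intensity ratios with
DNA-content cell-cycle staging, continuous-photobleaching (CP) mobility
decomposition, fluorescence correlation spectroscopy (FCS) with a triplet-3D
correlation model and Stokes–Einstein mass-ratio inference, quantification
of punctate intranuclear lamin structures, and 3D telomere-motion analysis.
Every analysis stage has a matching synthetic-data generator with stored
ground truth, so the whole pipeline is testable without any microscope.

It is written for cell biologists and microscopists who export TIFF stacks,
intensity traces and 3D spot trajectories and want a scripted, reproducible
alternative to one-off GUI plugins.

## The quantities at the core

- **N/P ratio.** Nuclei are segmented (Otsu threshold + watershed), each
  nucleus is split into a peripheral rim of width `rim` (default 0.8 μm)
  and the interior nucleoplasm. The ratio is
  `N/P = median(min-projection | nucleoplasm) / Q75(max-projection | periphery)`.
- **Cell-cycle stage.** Integrated DAPI density per nucleus is gated into
  G1 (2C) and S-G2 (up to 4C) populations.
- **CP immobile fraction.** A spot trace is decomposed as
  `I(t)/I0 = f·exp(−k_fast t) + (1−f)·exp(−k_slow t)`,
  where the fast-bleaching amplitude `f` is the immobile fraction.
- **FCS triplet-3D model.**
  `G(t) = [1 + Σ_j T_j(e^{−t/τ_trip,j} − 1)] · Σ_i ρ_i [1+(t/τ_D,i)^{a_i}]^{−1} [1+(t/τ_D,i)^{a_i}/k²]^{−1/2} + G_∞`,
  with beam waist `w0 = (V_eff/(π^{3/2}k))^{1/3}` and
  `D_i = w0²/(4τ_D,i)` (defaults `V_eff = 0.267 fl`, `k = 7.92`).
- **Stokes–Einstein mass ratio.** For spherical complexes of equal density,
  `D_a/D_b = (M_b/M_a)^{1/3}` — e.g. a 175 kDa lamin A–LAP2α complex
  versus 100 kDa lamin A alone predicts a diffusion ratio of **0.83**.
- **Telomere motion.** Tracks (50 points over 20.5 min) are drift/rotation
  corrected by SVD rigid registration, filtered to complete tracks, and
  summarized by convex-hull volume and time-averaged MSD (slope `6D` for
  free 3D diffusion).

## Worked example

```bash
lamindyn simulate npratio --seed 3 --n-nuclei 3 --out sim
lamindyn npratio sim/nuclei.tif --out ratios.csv
```

then, or equivalently through the scripted analyses:

```bash
python analysis/01_simulate_datasets.py
python analysis/02_np_ratio_cell_cycle.py
python analysis/03_photobleaching.py
python analysis/04_fcs_diffusion.py
python analysis/05_telomere_motion.py
```

which prints (abridged):

```
50 nuclei; mean N/P 0.246 (truth 0.250, error 1.5%)
time-lapse: worst pointwise error 0.1% (anchor frame 0)
wt: n=60, mean immobile fraction 0.254 (truth 0.254)
ko: n=60, mean immobile fraction 0.462 (truth 0.463)
arcsin t test: p = 7.53e-24, d = -2.32
D_WT/D_KO (fast species): measured 0.83, Stokes-Einstein prediction 0.83
WT vs LAP2a-KO hull volumes: Mann-Whitney p = 7.14e-41, d = 3.30
```

Reading the numbers: the automated N/P pipeline recovers the constructed
ratio of 0.25 to within 1.5% over 50 noisy nuclei; the CP cohorts built with
immobile fractions of 10–40% ("wild type") versus 30–60% ("knockout")
separate decisively on the arcsin scale; the FCS fits of the two simulated
cohorts give a fast-species diffusion-coefficient ratio of 0.83, matching
the Stokes–Einstein prediction for losing a 75 kDa binding partner from a
175 kDa complex; and the slow anomalous "wild-type" telomeres cover far
smaller motion volumes than the freely diffusing lamin-knockout-like ones.
Tables land in `results/`, simulated raw data in `scratch/data/`.

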