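# memquant

Quantitative analysis of stimulus-driven membrane recruitment of
cytosolic signaling proteins — the workflow used to show that a Smad
transcription factor is brought to the plasma membrane by binding the
phosphoinositide PI(4,5)P₂ before engaging its receptor kinase. The
package is for biophysicists and quantitative cell biologists who have
(a) equilibrium binding data from SPR or fluorescence anisotropy,
(b) dual-color single-molecule TIRF movies of a receptor and a candidate
binding partner, or (c) cell images to score membrane/nuclear
translocation and membrane lipid levels — and who want the published
quantities (Kd, fold selectivity, colocalization half-life, Fm/Fc,
Inuc/Icyto, mol% lipid) computed reproducibly from raw inputs.

## The models at the core

**Equilibrium binding.** Steady-state SPR responses are normalised to
fractional occupancy and fit to the one-site Langmuir isotherm

    RU/RUmax = 1 / (1 + Kd / P₀),

with Kd optimised on a log scale by damped nonlinear least squares.
Fluorescence-anisotropy titrations of labelled receptor-derived peptides
(ligand-excess regime, P₀ ≫ Pep₀) are normalised to
A_norm = (A − A_min)/(A_max − A_min) and fit to the same hyperbola, with
a free saturation amplitude absorbing incomplete saturation of the
titration. Affinity comparisons (fold = Kd_a/Kd_b; percent affinity
gain = 100·(Kd_a/Kd_b − 1)) and a selectivity report reproduce the
derived columns of the published Kd table, which ships with the package.

**Colocalization kinetics.** Receptor and partner molecules are
detected (difference-of-Gaussians + sub-pixel centroid), linked into
trajectories (optimal bipartite matching), and registered onto a common
coordinate frame (affine fit to fiducial beads). A partner molecule
within 400 nm of a receptor is colocalized; maximal consecutive-frame
runs longer than 0.2 s are dwell events, whose survival curve is fit to

    P = P₀ · e^(−k·t),      half-life = ln 2 / k,

estimating the dissociation rate of the complex. Stimulation time
courses of the half-life localise when receptor engagement peaks.

**Cell images.** Membrane translocation is the two-peak line-profile
ratio Fm/Fc; nuclear translocation is Inuc/Icyto from masks or
cross-sectional lines; TIRF recruitment curves are baseline-subtracted
masked means; ratiometric biosensor image pairs map through a supplied
calibration to spatially resolved lipid concentration in mol%.

Every stage has a seeded synthetic-data generator with paired ground
truth (`memquant.synthetic`), so the whole pipeline is testable without
instrument data.

## Worked example

```python
import numpy as np
from memquant import binding, coloc, synthetic

# --- Kd from a simulated SPR isotherm (true Kd = 100 nM) ---
conc = np.array([10, 25, 50, 100, 200, 500], dtype=float)
iso, true_kd = synthetic.simulate_isotherm(100.0, conc, noise_sd=0.02, seed=7)
est = binding.fit_langmuir_kd(iso)
print(f"Kd = {est.kd:.1f} ± {est.kd_se:.1f} {est.unit}")

# --- published-table selectivity ---
table = binding.load_reference_kd_table()
wt = table[table.variant == "WT"].set_index("surface")["kd"]
fold = binding.affinity_fold_change(wt["PC/PS"], wt["PC/PS/PI(4,5)P2"])
print(f"PI(4,5)P2 increases WT membrane affinity {fold:.1f}-fold")

# --- dissociation kinetics from simulated dwell times (k = 2 /s) ---
cfg = coloc.ColocConfig(frame_interval=0.05)
dwells = synthetic.simulate_dwell_times(2.0, 0.05, 5000, seed=4)
fit = coloc.fit_exponential_survival(dwells[dwells > 0.2], cfg)
print(f"k = {fit.k:.2f} /s, half-life = {fit.half_life*1e3:.0f} ms")
```

prints

```
Kd = 104.6 ± 2.1 nM
PI(4,5)P2 increases WT membrane affinity 5.6-fold
k = 2.02 /s, half-life = 343 ms
```

— the fitted Kd recovers the generating 100 nM to within a few percent;
the 5.6-fold ratio is the membrane-affinity gain conferred by
3 mol% PI(4,5)P₂; the survival fit recovers the simulated dissociation
rate, and the half-life is exactly ln 2/k.

A `memquant` command-line tool wraps the same stages
(`simulate`, `fit-binding`, `track`, `coloc`, `quantify`, `report`);
`memquant --show-config` prints the defaults.

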