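# lifespan-ec

Normative growth charts for the brain's *effective connectome*: directed,
signed coupling strengths among cortical regions estimated from resting-state
fMRI, charted across the human lifespan.

Functional connectivity (correlation of BOLD signals) is undirected and cannot
separate excitatory from inhibitory influence. Effective connectivity (EC)
instead comes from a generative model of neural dynamics: a linear
dynamic causal model `dx/dt = A x + C u`, whose coupling matrix `A` holds one
signed, directed weight per region pair (positive = excitatory, negative =
inhibitory; entry *(i, j)* is the influence of region *j* on region *i*). This
package implements the full analysis chain that turns per-scan regional BOLD
series into lifespan growth charts of the effective connectome:

1. **Regression DCM** (`lifespan_ec.rdcm`) — the linear DCM is moved to the
   frequency domain, where the DFT's differential property converts the coupled
   ODE into one Bayesian linear regression per target region,
   `Y_i = X θ_i + ν`, with `Y_i` the DFT of region *i*'s temporal derivative
   and the columns of `X` the region spectra. Each regression is inverted with
   conjugate Gaussian–Gamma variational Bayes, so a full `R × R` matrix costs
   `R` small regressions — whole-cortex EC in seconds per scan.
2. **Connectome metrics** (`lifespan_ec.metrics`) — global/within-network/
   between-network mean EC with excitatory and inhibitory splits,
   the network segregation index `NSI = (EC_W − EC_B) / EC_W`, the network
   integration index `NII = |EC_B,exc| + |EC_B,inh|`, and nodal EC strength
   (ECS, the row sum of incoming EC) with network averages.
3. **Growth modeling** (`lifespan_ec.trajectory`) — a penalized-spline mixed
   model `y_i(t) = f1(t) + f2(t)·sex_i + α_i + β_i + ε` in transformed age
   `t = log2(age + 1)`, with subject and site random intercepts, REML
   smoothing, and basis dimension `k = 5..14` selected by BIC. Curves carry
   pointwise normal-quantile confidence bands, with smoothing-parameter
   uncertainty propagated into the coefficient covariance.
4. **Peaks and velocities** (`lifespan_ec.peaks`) — the maturation peak is
   the largest interior local maximum of the fitted curve (sign-flipped for
   inhibitory metrics); its CI comes from resampling the age-smooth
   coefficient posterior (20,000 draws by default); the growth rate is the
   forward-difference derivative with respect to age.
5. **Trajectory patterns** (`lifespan_ec.patterns`) — K-means clustering of
   regional ECS growth curves, trajectory correlation matrices, early-life
   (<12 y) versus adult (>20 y) variability, and the first-principal-component
   developmental gradient across regions.
6. **Inference** (`lifespan_ec.stats`) — two-sided Wilcoxon rank-sum and
   signed-rank tests (exact at small n), Benjamini–Hochberg FDR, Cohen's d.

Because lifespan imaging cohorts are access-controlled, the package ships a
**synthetic cohort generator** (`lifespan_ec.synth`) that plants known lifespan
trajectories on the edges of stable coupling matrices and simulates BOLD
through the same forward model (Euler–Maruyama integration, canonical
double-gamma HRF, white observation noise at a stated SNR). Every stage is
therefore testable against ground truth, end to end, with no data download.

## Worked example

The numbered scripts under `analysis/` run the whole chain on a synthetic
20-region, 4-network cohort of 120 subjects (ages 10 days to ~96 years,
four acquisition sites, longitudinal repeats in infancy):

```bash
python analysis/01_simulate_cohort.py      # cohort + ground truth
python analysis/02_estimate_connectivity.py
python analysis/03_connectome_metrics.py
python analysis/04_fit_growth_curves.py
python analysis/05_peak_ages.py
python analysis/06_cluster_gradient.py
python analysis/07_group_statistics.py
```

Output of the peak step on this cohort (seed 0):

```
global_ec_exc peak: 6.99 y (95% CI 5.68-9.91, 20000 draws, 0 peakless draws dropped)
  fastest growth at 1.08 y, fastest decline at 0.03 y
  planted global peak 8.81 y -> error 1.82 y
```

The excitatory mean EC follows an inverted-U over the lifespan: a brief dip in
infancy, fastest growth around 1 year, a childhood maturation peak (here
estimated at 7.0 y, with the planted 8.8-y truth inside the 95% CI), and slow
decline thereafter. The overall mean EC at this desk scale is diluted by the
many zero edges and estimator shrinkage — step 04 reports its fitted curve as
essentially flat, which is the expected behavior at toy cohort sizes. Step 07
finds higher trajectory variability before 12 years than after 20 years in
every network (Cohen's d 0.4–1.3), the early-plasticity signature the growth
charts are designed to expose.

A single command runs the same pipeline with provenance and resume support:

```bash
lifespan-ec run --seed 7 --out-dir run/
```

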