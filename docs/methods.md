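# Methods

## The C4 model and its inversion

The forward model predicts net CO₂ assimilation of a C4 leaf as the
minimum of an enzyme-limited rate (Rubisco in the bundle sheath, fed by
PEP carboxylation in the mesophyll) and an electron-transport-limited
rate. Both branches couple demand to supply: the assimilation flux draws
mesophyll CO₂ (Cm) down through the mesophyll conductance gm, and
bundle-sheath CO₂ (Cs) balances C4-acid decarboxylation against leakage
through gbs. Because A appears on both sides, each branch is a scalar
fixed-point problem f(A) = A − demand(supply(A)) = 0. The demand is
non-increasing in A, so f is increasing and the root unique; we bracket
[−Rd−1, min(Vcmax,Vpmax)+1] (enzyme) or [−Rd−1, (1−x)Jt/3+1] (light) and
solve with Brent's method at xtol 1e−12. If endpoints fail to bracket, a
257-point scan locates the smallest root — the "supply limits demand"
physical branch. Solutions with Cm ≤ 0 raise a non-physical warning;
this is routine on whichever branch of min(Ac, Aj) is *not* binding at
low CO₂ and is suppressed in those contexts.

The transport-limited gross term uses the standard C4 form
Aj = [(1−x)·Jt/3]·(1 − γ*Os/Cs)/(1 + 7γ*Os/(3Cs)) − Rd. (The source
text's rendering of this equation is typographically garbled; the form
above is the standard one in the C4 modelling literature and should be
kept in mind when comparing against other implementations.) The
electron transport rate Jt is the smaller root of the non-rectangular
hyperbola, computed through the numerically stable larger-root/product
identity plus one Newton polish so the quadratic residual stays at
rounding level even for small curvature θ.

### Constants

The enzymatic constant set is a documented default drawn from the
standard C4 modelling literature, not asserted as any particular field
study's values, and fully overridable:

| constant | default | units | meaning |
|---|---|---|---|
| Kc | 1210 | µbar | Rubisco Michaelis constant, CO₂ |
| Ko | 292 | mbar | Rubisco Michaelis constant, O₂ |
| Kp | 82 | µbar | PEP carboxylation Michaelis constant |
| γ* | 0.000193 | – | half reciprocal Rubisco specificity |
| Os | 210 | mbar | bundle-sheath O₂ |
| gbs | 0.003 | mol m⁻² s⁻¹ bar⁻¹ | bundle-sheath CO₂ conductance |
| x | 0.4 | – | electron-transport share to the C4 cycle |
| φ | 2 | – | ATP per C4-cycle turn |
| Rm/Rd | 0.5 | – | mesophyll share of respiration |

CO₂ mole fractions (ppm) are treated as numerically equal to partial
pressures in µbar (1 bar total pressure). No temperature response is
applied: all parameters are at-measurement values. gm is fixed (default
1.0 mol m⁻² s⁻¹ bar⁻¹), not fitted. Mixed units are respected in code:
γ*·Os is converted to µbar (≈40.5) wherever it meets Cs.

### Two-stage fitting

Stage 1 fits the Ai curve with the transport-limited branch for
(Jmax, θ, PSabs, Rd); Rd is anchored by the dark step (I = 0) through
its initial value. Stage 2 holds those fixed and fits (Vcmax, Vpmax) to
the ACi curve with the full min(Ac, Aj) model; the light-limited rate
per step does not depend on the stage-2 parameters and is precomputed.
Both stages minimise unweighted squared error in A with bounded
trust-region least squares from 5 seeded multi-starts (first start
heuristic, the rest log-uniform in bounds; best SSE wins, ties to the
smaller parameter norm). Bounds: Jmax [50, 1000], θ [0.05, 0.95], PSabs
[0.05, 0.9], Rd [0.001, 10], Vcmax [5, 150], Vpmax [20, 1200]. θ can be
fitted freely (module default) or pinned at its conventional 0.3
(`fix_theta`); the pipeline pins it, which roughly halves the Jmax error
at the reference noise level.

**Vcmax identifiability.** At sorghum-like trait magnitudes the enzyme
plateau (≈Vcmax − Rd) and the transport ceiling (≈(1−x)Jt/3 at the
protocol's 1800 µmol m⁻² s⁻¹ PAR) are close: for low-Jmax leaves the
ACi curve saturates by electron transport and carries no information on
Vcmax. After fitting, the pipeline perturbs Vcmax by 5% and measures the
largest change in the predicted curve; below 0.4 µmol m⁻² s⁻¹ per unit
Vcmax — the sensitivity needed to resolve a ~10% Vcmax change above the
~1 µmol m⁻² s⁻¹ step noise — the estimate is flagged unusable (as are
fits pinned at a Vcmax bound). Such plots keep their Vpmax/Jmax values
but are excluded from Vcmax training labels. This is the desk-scale
analogue of field ACi curves that cannot be fitted sensibly.

Fitted tables are screened with strict extreme-value rules — Vcmax > 65,
Vpmax > 750, Jmax > 700 µmol m⁻² s⁻¹ — applied per trait, so each trait
keeps its own valid plot set.

## Spectral processing

Band lookup is nearest-wavelength (ties to the lower band), no
interpolation — sensor bands are ~2.2 nm apart, well inside the index
definitions' tolerance. The NDVI mask is strict (> 0.5): a pixel at
exactly 0.5 is background. Plot reflectance is the arithmetic mean over
retained pixels only; plots with zero retained pixels are flagged empty
and excluded downstream, and a retained fraction under 1% raises a
warning flag. TVI uses the standard bracketing
0.5·[120·(ρ750−ρ550) − 200·(ρ670−ρ550)] (the printed variants of this
formula circulating in the applied literature have unbalanced
parentheses). A zero denominator reports that index as missing for the
plot. No shadow, sun-angle or BRDF correction is applied beyond the
mask.

## Chemometrics

**Index subsetting.** Indices are standardised and decomposed by PCA;
pairs with |r| > 0.9 are linked into connected components and each
component keeps the member with the largest squared-loading sum on PCs
1–2 (ties lexicographic). Constant or missing-valued indices are dropped
with a warning. An analyst-chosen subset can be supplied as an override.

**Stepwise regression** is bidirectional from the intercept-only model
under OLS AIC (Gaussian likelihood, k = 2), applying the single
add/remove with the largest AIC decrease until none decreases it;
rank-deficient candidate designs are skipped; deterministic given column
order. A property worth knowing: AIC admits a spurious regressor with
probability P(χ²₁ > 2) ≈ 16% per candidate, independent of sample size
and noise scale, so "selects exactly the true set" is only a
high-probability event for very small candidate pools.

**PLSR** mean-centres the 272-band spectra (no per-band scaling by
default; a `scale` switch exists) and fits up to 25 latent variables.
For each left-out plot one full-depth PLS fit yields nested predictions
for every component count via the coefficient identity
B_k = W_k(P_kᵀW_k)⁻¹q_k. The component count is the smallest whose LOOCV
RMSEP is within one standard error of the global minimum, with the
standard error taken on the *paired* per-observation difference of
squared errors against the minimiser — errors are strongly correlated
across component counts, and the marginal SE would grossly over-shrink
the selection. Reported R² is by default the squared Pearson correlation
between cross-validated predictions and observations (scatter-plot
convention); 1 − SSE/SST is available. RMSE is also expressed as % of
the trait mean. Note that the squared-Pearson convention is degenerate
for the exact mean-only predictor under LOOCV (predictions are then
perfectly anti-correlated with the data), so mean-only baselines are
compared on the sum-of-squares convention.

## Mixed model and heritability

Per trial and trait: y = Xβ + Z_g u_g + Z_r u_r + Z_c u_c + e with fixed
intercept and scaled linear row/column trends, independent random
effects and residuals. REML is maximised over log variance ratios
(L-BFGS-B from three starts, ratios profiled against σ²_e on the n×n
covariance); genotype BLUPs and their prediction-error variance come
from the fitted covariance directly. SED̄ is the mean over genotype
pairs of the SE of their BLUP difference (all pairs up to 200 genotypes,
a seeded 5000-pair sample beyond). H² = 1 − SED̄²/(2σ²_g) is not
clipped; σ²_g at its zero boundary (ratio < 0.02, i.e. genetically
negligible) reports H² = 0 with a flag, and negative H² values are
reported flagged. This variance structure is deliberately simpler than a
full field-trial analysis: no AR1×AR1 spatial residual correlation and
single-trial fits only, so its validation target is parameter recovery
under its own model, which the tests exercise (balanced-design REML
matches closed-form ANOVA to 1e−6; H² matches the line-mean formula
σ²_g/(σ²_g+σ²_e/r) in the balanced limit).

The Table-style genotype summary reports min/max/mean of predicted
genotype values (intercept + BLUP), SED̄/√2 as the average standard
error, and H².

## The synthetic generator

The generator defines the study conditions under which the pipeline is
validated.

*Traits.* Genotype values for (Vcmax, Vpmax, Jmax, SLN, LMA) are
multivariate normal, truncated positive, with means (51.1, 408, 409,
2.0, 50) and genetic SDs (4.5, 90, 70, 0.22, 5.5) calibrated to
published sorghum field summaries; correlations are Vcmax–SLN 0.6,
Jmax–SLN 0.5, 0.2 elsewhere. Plot values add independent residuals of
roughly 0.45× the genetic SD, giving generalised heritabilities near
0.85 under partial replication. Percent leaf N is derived so that
SLN = (%N/100)×LMA holds exactly at both genotype and plot level.

*Curves.* ACi observations come from the full min(Ac, Aj) model at the
standard CO₂ sequence (200, 100, 50, 250, 400, 650, 800, 1000, 1200,
1400 ppm, PAR 1800); Ai observations come from the transport-limited
branch at the light sequence (2000 … 15, 0 µmol m⁻² s⁻¹, CO₂ 400) — the
light-response protocol at ambient CO₂ is designed to trace that branch,
and it is the model the Ai fit inverts. Noise is multiplicative
(CV 2%) plus an additive instrument floor (SD 0.2 µmol m⁻² s⁻¹); Ci/Ca
is jittered (SD 0.02) around 0.4 with the realised Ci recorded, as a gas
analyser would. With noise off the curves equal the forward model
exactly. The generator's PSabs is 0.45 (≈0.85 leaf absorptance × ~0.5
PSII share): this keeps the transport ceiling above the Rubisco plateau
for most genotypes, reproducing the observed field fittability of ACi
curves at these trait magnitudes; at 0.35 about half of simulated curves
are transport-capped and Vcmax is widely unidentifiable, which
contradicts how often field fits succeed.

*Spectra.* The plant endmember is built from smooth basis functions:
a green-peak visible background; a chlorophyll trough at 670 nm
deepening with SLN; a red-edge logistic whose inflection shifts with SLN
(mildly nonlinear, via tanh) and steepens with Jmax; a NIR plateau
scaling with LMA and weakly with Vcmax; narrow features at 531 nm
(Vcmax), 600 nm (Vpmax) and 870 nm (Jmax); and a structural dip at
955 nm scaling with LMA. The 870 nm feature is deliberately placed away
from the wavelengths any of the 15 indices sample, so the full spectrum
carries information the index set cannot — the mechanism by which PLSR
outperforms index regression here, mirroring what is reported for field
data. Coupling amplitudes were chosen so the desk-scale cross-validated
predictabilities bracket the R² range reported for field canopies
(≈0.68–0.93). Plant pixels share the plot endmember (plus one smooth
plot-level perturbation, SD 0.003) under log-normal per-pixel brightness
(SD 0.06) and band-correlated noise (SD 0.008); soil is flat at 0.25
with a slight slope. Plant NDVI > 0.6 and soil NDVI < 0.2 by
construction, so mask membership is exact. Default plots carry 80
pixels, 25% soil.

*What passing does and does not show.* The generator's trait–spectrum
link is low-dimensional, smooth, and noise-limited mainly by a
plot-level endmember perturbation; real canopies add structure the
generator does not emulate (BRDF and sun-angle effects, canopy
architecture, water bands beyond 997 nm, atmospheric variation,
senescence gradients). Passing the end-to-end checks therefore
establishes the correctness and internal consistency of the pipeline's
computations under stated conditions — not that field predictabilities
of any particular magnitude are guaranteed.

## Reference problem sizes

The shipped workflow simulates 150 training plots (120 genotypes) and
600 target plots (450 genotypes), 80 pixels per plot — sizes chosen so
the full workflow, the 200-replicate fit-recovery study and the REML
recovery study all run comfortably on a single CPU while leaving the
statistical conclusions stable. The full demo completes in about a
minute and a half.

## Known limitations

- Vcmax ground truth from two-stage fitting is intrinsically fuzzy
  where enzyme and transport rates co-limit; the identifiability gate
  trades coverage (≈15% of plots excluded) for label quality.
- The mixed model's simplified variance structure will underfit trials
  with strong spatial autocorrelation.
- PLSR models serialise coefficients and centring only; refitting needs
  the original spectra.
- The squared-Pearson R² convention is optimistic when predictions are
  biased but correlated; the sum-of-squares convention is provided.
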