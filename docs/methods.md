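# Methods

`dfmri` implements a diffusion-functional-MRI analysis for block-design
rodent experiments: fast mean-diffusivity (MD) and mean-kurtosis (MK)
mapping per condition and diffusion time, comparison of candidate
diffusion-time-dependence models, and ROI-level rest-vs-stimulus inference,
together with a BOLD arm and a synthetic study generator that makes every
stage testable without scanner data.

## Acquisition model and bookkeeping

One diffusion acquisition is a two-shell scheme at a single diffusion time
Δ: 3 b=0 measurements plus 9 gradient directions at b = 1 and 2 ms/µm²
(21 measurements per repetition), repeated twice per condition. The block
paradigm alternates 28 s rest / 28 s stimulus; at TR = 2 s over 3 epochs
this yields 84 volumes, 42 per condition, and condition averaging produces
19 images per condition (one pooled b0 + 18 diffusion weightings). The BOLD
paradigm spans 6 epochs at TR = 1 s (336 volumes, 168 per condition).
Volumes are labelled by half-open time bins [t, t + TR); each epoch is rest
first. Within a condition, measurements cycle through the scheme in order
(b0s first, then direction-major, b-minor); the true within-interval
ordering of the in-vivo protocol is not public, and nothing downstream
depends on it because estimation uses condition averages only.

## Fast MD/MK estimation

Per direction n, the two-shell closed form inverts the cumulant truncation
ln S(b,n) = ln S0 − b·D(n) + (1/6)·b²·D(n)²·K(n):

    D(n) = (b2² y1 − b1² y2) / (b1 b2 (b2 − b1)),
    K(n) = 6 (b2 y1 − b1 y2) / (D(n)² b1 b2 (b2 − b1)),

with y_i = −ln(S(b_i)/S0). MD is the plain directional mean; MK defaults to
the tensor-mean convention MK = (1/9) Σ (D(n)/MD)² K(n), which equals the
mean of the kurtosis tensor when the direction set satisfies the fourth-order
isotropy condition (a plain mean of K(n) is available by flag). The shipped
9-direction set was obtained by least-squares moment matching so that
(1/9) Σ n nᵀ = I/3 and (1/9) Σ n⊗n⊗n⊗n equals the isotropic fourth moment,
both to machine precision; `verify_direction_set` re-checks these identities
against random tensor pairs and gates any user-supplied set. Signals are
clipped below at 10⁻⁶·S0 before logs; voxels with nonpositive signals,
clipped signals, any D(n) ≤ 0, non-finite estimates, MD ≤ 0 or MK < 0 are
excluded from all downstream statistics (unphysical mask).

## Time-dependence models

Five candidates describe MD(Δ) and MK(Δ):

- 1D structural disorder: c∞ + 2A·Δ^(−1/2) (MD and MK variants),
- 2D–3D structural disorder: c∞ + A·ln(Δ/t_c)/Δ (MD and MK variants),
- two-compartment exchange (MK only):
  MK(Δ) = K0·(2 t_ex/Δ)·[1 − (t_ex/Δ)(1 − e^(−Δ/t_ex))],

with K0 the Δ→0 kurtosis and t_ex the exchange time. The exchange form is
evaluated by series expansion for Δ/t_ex < 10⁻³ to avoid cancellation. Fits
are unweighted nonlinear least squares on the 5-point mean curve (an
SE-weighted mode exists) with a fixed multi-start grid: t_ex ∈ {10, 25, 50,
100, 200} ms with K0 = max(curve) for the exchange model; c∞ = min(curve)
with A from the first two points for the disorder models (t_c grid
{0.1, 1, 5, 10, 20} ms). Bounds: t_ex ∈ (1, 10³) ms, t_c ∈ (10⁻³, 10³) ms,
K0 ∈ (0, 10); amplitudes unbounded in sign. Parameter covariance is the
Jacobian-based (JᵀJ)⁻¹ scaled by RSS/(n−k). Candidates are ranked by
AICc = n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1) with n = 5 (mean-curve points);
fits with n ≤ k+1 or failed convergence are excluded, and exact ties go to
the model with fewer parameters. K0 is fitted freely (not fixed).

## ROI statistics

ROI means use valid voxels only. Percent change is 100·(stim − rest)/rest
per diffusion time; the report keeps the maximum-magnitude change across
diffusion times with its sign and Δ. The condition test is a linear mixed
model with condition and diffusion time (categorical) as fixed effects,
a subject random intercept and run-within-subject variance component,
fitted by ML; the p-value is the χ²(1) likelihood-ratio test of the
condition term (Wald/Satterthwaite alternatives were not implemented; LRT
is the simplest defensible default). Singular or failed fits fall back to a
condition-only fixed effect with a subject intercept and are flagged.
Benjamini–Hochberg FDR is applied separately per metric family (MD, MK,
BOLD); stars are *, **, *** at q < 0.05/0.01/0.001.

## BOLD arm

Each epoch is normalized by its mean signal over the 14 s preceding
stimulation onset; the response function is the pointwise mean across
epochs (and runs/subjects when pooled). Condition amplitudes average all
rest and all stimulus timepoints (one estimate ± SE per condition), with a
Welch t-test within a series and the mixed model across runs. The voxelwise
GLM regresses each series on [intercept, discrete-cosine high-pass basis
(cutoff 0.01 Hz), boxcar]; activation is one-sided (positive t) with
Bonferroni family-wise voxel correction at 0.05 over the analysis mask and
no cluster-size threshold. When a cortical reference mask is available,
voxels below 10% of the mean cortical signal are removed first (surface-coil
depth cutoff; mean rather than median, an undocumented detail of the
original pipeline).

## Synthetic studies

The generator's ground truth is a two-compartment exchange substrate:
fractions f_i, diffusivities D_i, exchange time t_ex. MD = Σ f_i D_i is
time-independent; K0 = 3·Var_f(D)/MD², and MK(Δ) follows the exchange form
above. `substrate_from_moments` constructs the equal-fraction substrate
realizing a target (MD, K0, t_ex). Noise-free diffusion signals use the
same second-order cumulant form the estimator inverts — deliberately, so
estimator round-trips are exact and fitting behaviour is isolated from
model truncation bias; a directional cumulant mode (`cumulant_signal_tensor`)
takes a diffusion/kurtosis tensor pair for anisotropic phantoms. Rician
noise adds independent Gaussians of width σ = S0/SNR on two channels of the
complex signal and takes the magnitude.

The default study mirrors the in-vivo protocol: 10 subjects, 5 runs each
except two subjects with 4 (48 runs), forepaw alternating run-to-run,
5 diffusion times per run, plus one BOLD series per run. Regions are slabs
of a labelled grid sized by anatomically motivated weights — subcortical
regions (thalamus-, striatum-, hippocampus-like) largest — reflecting the
wide ROI-size spread real atlas segmentations produce, which is what makes
deep low-SNR ROI means usable at all. The b0 SNR interpolates from 20 in
cortical regions to 10 at depth (surface-coil profile). Default effects:
MD/MK decrease in the S1FL-like region (−1.1%/−4.9%, stimulus t_ex
45.1 ms vs. rest 53.8 ms), MD decrease in the M1-like region, MD/MK
increases (+1.3…+3.1%) in the S2-like and subcortical-like regions, null
in two control regions; effects apply only to contralateral (right-forepaw)
runs. BOLD boxcar amplitudes: +1.2% (S1FL-like), +0.3% (S2), +0.2% (M1),
−0.1% (CPu), 0 elsewhere, with 0.1%/min drift and 0.5% Gaussian noise.
Percent effects enter as scalings of MD and K0; because stimulus and rest
exchange times differ in the S1FL-like region, the realized MK(Δ) change
there varies with Δ (larger than the K0 scaling alone) while keeping its
sign — the injected values are calibration targets, not guaranteed
observables. At SNR 10 the nonlinear estimator and unphysical masking
attenuate observed MK changes (a +2.4% injected thalamic K0 change is
observed as ≈ +1.2%); signs are preserved, which is what the end-to-end
test claims.

Seeding: one master seed; each series derives its stream from
`SeedSequence(master, spawn_key=(rat, run, Δ-index, kind))`, so any single
series is reproducible in isolation.

What the generator does not emulate: EPI distortion, motion, slice-timing,
partial-volume anatomy, vascular (BOLD-like) contamination of the diffusion
signal, and spatial noise correlations. Passing tests therefore demonstrate
correctness of the estimators and inference under the stated noise model,
not robustness to those real-data artifacts.

## Problem sizes and numerical choices

Test problem sizes are chosen to keep the default suite within minutes on
one CPU: calibration tests use 500 mixed-model null replicates (4 subjects
× 3 runs × 5 Δ × 2 conditions) and 2000 BH null families; model-recovery
uses 200 noisy replicates per generating model; the end-to-end sign test
runs 20 replicates of the full 48-run design on a 16×16×8 grid. Optimizer
tolerances are 10⁻¹⁴ (xtol/ftol/gtol) so that noiseless round-trips recover
published operating points well inside the 0.1 ms / 0.005 reporting
tolerances. Degenerate inputs are explicit errors: Δ < δ, non-unit
directions, intervals not multiples of TR, missing measurements per
condition, zero rest means, single-subject mixed tests, n ≤ k+1 AICc.

## Known limitations

- The mixed-model LRT p-value is asymptotic; at very small designs it can
  be mildly mis-calibrated (the type-I test pins it to [0.03, 0.07]).
- The exchange and 1D-disorder MK models are near-degenerate on a 5-point
  grid (the in-vivo analysis reaches the same conclusion); AICc comparisons
  between them are meaningful only in aggregate.
- The GLM's Bonferroni correction ignores spatial correlation (none exists
  in the synthetic data); random-field corrections are out of scope.
- Anisotropy is supported in signal synthesis and estimation cross-checks,
  but the study generator uses isotropic voxels.
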