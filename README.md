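# dfmri

Diffusion-functional-MRI analysis for block-design experiments.

Neural activity changes tissue microstructure — cells swell, the
extracellular space gets more tortuous, membrane permeability shifts — and
diffusion MRI can see it. During alternating 28 s rest / 28 s stimulus
blocks, a fast two-shell protocol (3 b0 + 9 directions × b ∈ {1, 2} ms/µm²,
two repetitions per condition) yields voxel-wise mean diffusivity (MD) and
mean kurtosis (MK) per condition at each of several diffusion times Δ.
`dfmri` implements that pipeline end to end for researchers analyzing (or
simulating) such experiments: protocol bookkeeping and condition averaging,
closed-form MD/MK estimation with unphysical-voxel masking, fitting and
AICc-ranking of diffusion-time-dependence models, ROI-level rest-vs-stimulus
statistics (linear mixed models + Benjamini–Hochberg FDR), and a BOLD arm
(epoch normalization, condition averages, boxcar GLM with family-wise voxel
correction).

The core quantities: per direction n, the cumulant truncation
`ln S(b,n) = ln S0 − b·D(n) + (1/6)·b²·D(n)²·K(n)` is inverted exactly from
two shells; MD = ⟨D(n)⟩ and MK = ⟨(D(n)/MD)²·K(n)⟩ over a 9-direction set
constructed so these directional averages equal the true tensor means. The
time dependence of MK is compared between structural-disorder power laws
(1D: K∞ + 2A·Δ^(−1/2); 2D–3D: K∞ + A·ln(Δ/t_c)/Δ) and the two-compartment
exchange (Kärger) model

    MK(Δ) = K0 · (2·t_ex/Δ) · [1 − (t_ex/Δ)(1 − e^(−Δ/t_ex))],

whose exchange time t_ex is the membrane-permeability readout: a shorter
t_ex under stimulation means faster transmembrane water exchange.

A synthetic-data module generates whole studies (subjects × runs ×
diffusion times × conditions, DWI + BOLD + labels + manifest) from
two-compartment exchange substrates with region-specific effects and a
surface-coil-like SNR profile, so every downstream stage is testable
without scanner data.

## Worked example

Simulate one region ("S1FL-like", b0 SNR 20) whose stimulus condition has
1.1% lower MD, 4.9% lower K0 and a shorter exchange time (45.1 ms vs.
53.8 ms), acquire the full five-Δ protocol, estimate MD/MK per condition,
and fit the exchange model to the MK(Δ) curves:

```python
import numpy as np
from dfmri.acquisition import (BlockDesign, average_conditions,
                               build_default_scheme, schedule_block)
from dfmri.fastdki import estimate_md_mk, mask_unphysical
from dfmri.synth import (PROTOCOL_DELTAS, PhantomSpec, RegionSpec,
                         substrate_from_moments, synthesize_dwi)
from dfmri.timedep import TimeDependenceCurve, compare_models

rest = substrate_from_moments(md=0.70, k0=0.86, t_ex=53.8)
stim = substrate_from_moments(md=0.70 * 0.989, k0=0.86 * 0.951, t_ex=45.1)
phantom = PhantomSpec(labels=np.ones((12, 12, 6), dtype=int),
                      regions={1: RegionSpec("S1FL", rest, stim, snr=20.0)})
design = BlockDesign(n_epochs=3, rest_s=28, stim_s=28, tr=2.0)

curves = {"rest": [], "stimulus": []}
for i, delta in enumerate(PROTOCOL_DELTAS):
    scheme = build_default_scheme(delta)          # 21 measurements x 2 reps
    schedule = schedule_block(design, scheme)     # 84 volumes, 42/condition
    series = synthesize_dwi(phantom, scheme, schedule, seed=10 + i)
    for cond_set in average_conditions(series, schedule, scheme):  # 19 images
        pmap = mask_unphysical(estimate_md_mk(cond_set, scheme))
        md = pmap.md[pmap.valid_mask].mean()
        mk = pmap.mk[pmap.valid_mask].mean()
        curves[pmap.condition].append(mk)
        print(f"Delta={delta:4.1f}  {pmap.condition:<8}  MD={md:.3f}  MK={mk:.3f}")

deltas = np.array(PROTOCOL_DELTAS)
for cond, mk in curves.items():
    comp = compare_models([TimeDependenceCurve(deltas, np.array(mk),
                                               metric="MK", condition=cond)])
    fit = comp.fits[("MK", cond, "contralateral")]["karger_mk"]
    print(f"{cond}: K0 = {fit.params['K0']:.2f}, t_ex = {fit.params['t_ex']:.1f} "
          f"+/- {fit.se['t_ex']:.1f} ms")
```

Output:

```
Delta= 9.5  rest      MD=0.703  MK=0.812
Delta= 9.5  stimulus  MD=0.696  MK=0.760
Delta=15.0  rest      MD=0.708  MK=0.798
Delta=15.0  stimulus  MD=0.695  MK=0.729
Delta=20.0  rest      MD=0.704  MK=0.760
Delta=20.0  stimulus  MD=0.697  MK=0.711
Delta=25.0  rest      MD=0.702  MK=0.725
Delta=25.0  stimulus  MD=0.694  MK=0.683
Delta=30.0  rest      MD=0.705  MK=0.720
Delta=30.0  stimulus  MD=0.696  MK=0.663
rest: K0 = 0.87, t_ex = 46.9 +/- 6.4 ms
stimulus: K0 = 0.81, t_ex = 46.7 +/- 1.9 ms
```

MD sits near 0.70 µm²/ms and is Δ-independent; MK decays with Δ and is
lower under stimulation at every Δ (the injected effect). Fitting the
exchange model to each 5-point MK(Δ) curve recovers a zero-time kurtosis
K0 near the generating values and exchange times in the tens of
milliseconds; at single-run noise the rest/stimulus t_ex difference is
within its uncertainty, which is why the full pipeline pools runs and
subjects before fitting.

## Whole-study pipeline

```sh
dfmri simulate --out study/ --seed 1 --rats 2 --runs 4
dfmri estimate --study study/
dfmri analyze  --study study/
```

`simulate` writes a study tree (NIfTI series, gradient tables, schedule
TSVs, manifest), `estimate` produces MD/MK/valid-mask maps per run,
condition and diffusion time, and `analyze` writes the ROI table, the
rest-vs-stimulus change report (percent changes per Δ, maximum-magnitude
change, mixed-model p-values, FDR q-values and stars), the
time-dependence model-comparison table, and the BOLD reports. See
`docs/methods.md` for the models, conventions, defaults and limitations.

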