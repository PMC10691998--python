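# nfkbcap

How many distinct antigen densities can a CAR T cell's NFκB pathway
actually tell apart?  `nfkbcap` treats CAR-4-1BB–mediated NFκB activation
as a noisy communication channel: a deterministic kinetic model maps an
antigen surface density *S* (molecules/µm²) to a nuclear-NFκB response
*R*, a lognormal cell-to-cell variability layer turns that map into a
population of heterogeneous channels, and information-theoretic
estimators score the result — channel capacity in bits, discrimination
error rates in percent, and the mutual information actuated by candidate
antigen distributions.  It is aimed at systems/synthetic biologists who
want quantitative, reproducible estimates of signaling fidelity for
engineered receptors.

## The model and the statistics

**Signaling.**  A mass-action ODE system follows the 4-1BB chain: antigen
binds the CAR, TRAF2 assembles a transient signalosome, the signal relays
stoichiometrically through RIP1-ubiquitination and TAK to IKKβ, whose
activity is a ~5 min pulse terminated by auto-deactivation.  IKKβ
degrades IκBα, releasing NFκB to the nucleus; peak nuclear NFκB (~30 min
after antigen addition) is the response, read absolutely (R_abs) or as
fold change over baseline (R_fold).  Disabling IKKβ deactivation — the
in-silico perturbation — makes kinase activity persistent and left-shifts
the dose-response curve.

**Noise.**  Each cell's protein totals are independent lognormals with
median at the nominal value and one shared scale parameter σ (the "noise
level"); a mask selects the variable proteins (all seven, or with the
NFκB/IκBα pools pinned).

**Information.**  With n equiprobable probe levels chosen so the
activations they elicit are evenly spaced, the mutual information

    I(S; R) = H(S) − H(S|R),   H(S) = log2 n

is estimated with k-nearest-neighbor estimators (Kraskov for
continuous–continuous, Ross for discrete–continuous); n grows until
I stops increasing, and the maximum is the channel capacity of a single
activation event.  Two-anchor discrimination ("low" = 5.5% activation,
"high" = 96%) is scored by kernel-density likelihoods: a high-stimulated
response more likely under the low-response density is a false negative.

See `docs/methods.md` for assumptions, parameter choices and known
limitations.

## Worked example

```python
import nfkbcap as nc

params = nc.build_default_parameters()          # calibrated kinetic set
resting = nc.pre_stimulation_steady_state(params)
traj = nc.simulate_response(params, resting, antigen=70.0)
m = nc.response_metrics(traj)
print(f"baseline nuclear NFkB: {m.baseline_nuclear_nfkb:.4f}")
print(f"peak nuclear NFkB:     {m.peak_nuclear_nfkb:.4f}")
print(f"fold change:           {m.fold_change:.1f}")
print(f"peak time:             {m.peak_time:.1f} min")
print(f"IKKb pulse width:      {m.ikkb_pulse_width:.2f} min")

curve = nc.dose_response(params)
print(f"probe anchors: low {curve.anchor_low:.2f}, "
      f"high {curve.anchor_high:.1f} molecules/um^2")
```

prints

```
baseline nuclear NFkB: 0.0018
peak nuclear NFkB:     0.0650
fold change:           35.3
peak time:             30.5 min
IKKb pulse width:      6.88 min
probe anchors: low 0.67, high 58.2 molecules/um^2
```

At a high antigen density the cell releases most of its NFκB in a
transient nuclear spike — a 35-fold rise over baseline peaking half an
hour after engagement, driven by a brief IKKβ pulse.  The probe anchors
are the antigen densities eliciting 5.5% and 96% of the saturating
response; they bracket the pathway's usable dynamic range and seed the
capacity heuristic's two-level alphabet.

Population-level surfaces run through the CLI (a thin layer over
`nfkbcap.experiments`); every run writes a tidy CSV plus a JSON manifest
and is byte-reproducible from its seed:

```sh
nfkbcap capacity --scale desk --seed 1 --out results/
nfkbcap errors   --scale desk --seed 1 --out results/ --perturb both
nfkbcap trialmi  --scale desk --seed 1 --out results/
nfkbcap report   --out results/
```

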