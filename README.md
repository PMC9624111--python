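# supertx

A hybrid continuous/stochastic simulator of transcription-generated DNA
supercoiling in multi-gene circuits, for researchers studying how *gene
syntax* — the relative order and orientation of neighboring genes — shapes
expression, noise, and dynamic coupling.

## The model

Transcription is a mechanical process. An elongating RNA polymerase must
rotate relative to the DNA helix (ω₀ ≈ 1.85 rad/nm of travel); the drag of
the nascent transcript resists that rotation, so part of the required
twist is pushed into the template instead — positive supercoiling ahead of
the polymerase, negative supercoiling behind (the twin-domain picture).
Because supercoiling spreads much faster than polymerases move, the
supercoiling density σ is uniform between consecutive barriers (polymerases
and domain walls):

    σ = (φᵢ − φᵢ₊₁) / (ω₀ (zᵢ₊₁ − zᵢ))

where z, φ are each barrier's position and local excess twist. Each
polymerase carries four coordinates (position z, nascent-RNA length x,
excess twist φ, rotation θ) coupled by groove tracking,
ω₀ ż = θ̇ + φ̇, and a torque balance in which the DNA restoring torque
τ(σ) and the twist drag χφ̇ oppose the rotational drag η·xⁿ·θ̇ of the
transcript. τ(σ) follows Marko's two-phase closed form (elastic twist,
torque plateau during plectoneme coexistence, plectonemic branch), and the
translocation velocity stalls sigmoidally when either the front or rear
torque magnitude approaches the stall torque (τ_s = 12 pN·nm, width 3).

Supercoiling feeds back on initiation: loading a polymerase inserts
~1.2 turns of twist, so the binding energy acquires a supercoiling term
E_sc = 1.2·2π·τ(σ) (+ α·τ₀·σ² in the second-order model), and each
promoter fires with instantaneous rate r(S)·e^(−E_sc/k_BT) — a
time-varying hazard that the integrator tracks exactly alongside the ODE.
Discrete regulation (Hill repression on mRNA counts, dimer/occupancy
networks, degradation, topoisomerase relaxation) runs embedded in the same
simulation, so toggle switches and the zebrafish her1–her7 segmentation
clock are just configurations.

## Worked example

```python
import numpy as np
from supertx import build_two_gene
from supertx.dynamics import run_ensemble
from supertx.analysis import ensemble_cross_correlation, first_positive_side_peak

# head-to-head (convergent) reporter + inducible gene, equal induction
# switched on at 10,000 s, linear boundaries
preset = build_two_gene("convergent", induction=1.0, duration=40000.0)
runs = run_ensemble(preset, 8, base_seed=100)

t = runs[0].trajectory["time"].to_numpy()
post = t >= 10000.0
rep = [r.trajectory["reporter_mRNA"].to_numpy()[post] for r in runs]
adj = [r.trajectory["adjacent_mRNA"].to_numpy()[post] for r in runs]
print("mean mRNA:", round(np.mean(rep)), "and", round(np.mean(adj)))

lags, cc = ensemble_cross_correlation(rep, adj, dt=10.0, max_lag=15000.0)
print("correlation at zero lag:", round(cc[np.argmin(np.abs(lags))], 2))
peak = first_positive_side_peak(lags, cc, min_lag=600.0)
print("side-peak offset:", round(abs(peak) / 3600.0, 2), "h")
```

prints

```
mean mRNA: 179 and 141
correlation at zero lag: -0.97
side-peak offset: 2.35 h
```

The two convergently oriented genes express at similar average levels but
almost never simultaneously: the gene that is transcribing pressurizes the
shared domain with positive supercoiling, silencing its neighbor until its
own burst collapses. The strong anti-correlation at zero lag together with
positive side peaks at ±2–2.5 h is the signature of that slow either-or
alternation.

## Command line

```
supertx preset fig5-toggle --scale 0.1 --out presets/   # emit experiment configs
supertx simulate presets/fig5_toggle_convergent.yaml --seed 3 --out run/
supertx ensemble presets/fig5_toggle_convergent.yaml --out ens/
supertx analyze ens/
```

Every config is a single YAML file (schema-validated, unknown keys
rejected); every artifact carries a provenance header with the config hash
and seed.

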