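# kvgating

Markov-model simulation and analysis of voltage-sensor gating currents
in homotetrameric and 3:1 heterotetrameric voltage-gated K⁺ channels.

A channel is modelled as three identical "common" voltage-sensor
subunits plus one "distinct" subunit (equal to the common one for the
homotetramer). Each sensor makes a single closed→activated transition
with exponentially voltage-dependent rates
`α(V) = α₀·exp(z_αδ_α·V/V_T)`, `β(V) = β₀·exp(−z_βδ_β·V/V_T)`;
once all four sensors are activated a final voltage-independent
concerted step opens the pore. The aggregated master equation has 9
states (8 closed/activated combinations + open) and is solved exactly
with matrix exponentials (Q-matrix approach).

On top of the kinetic core the package provides:

- **protocol engine** — episodic step protocols (ON-gating family,
  conditioning-prepulse/Cole–Moore family), deterministic occupancy
  propagation, gating-current and ionic-current synthesis, and an
  exact-jump Gillespie simulator for stochastic channel populations;
- **analysis** — ON-charge integration, Q–V construction, single and
  double Boltzmann fits, apparent charge from the slope
  (`z = k_B·T/(slope·e₀)`), 1–2-exponential decay fits with weighted
  time constants, τ–V curves, decay-phase trace-crossing detection,
  activation-delay (Cole–Moore) fits, and G–V curves from peak ionic
  currents;
- **synthetic data** — whole-cell-style recordings: Gaussian current
  noise, a causal 4-pole low-pass Bessel filter (−3 dB at the cutoff),
  decimation to the acquisition rate, linear leak, capacitive
  transients, P/8 subtraction, and mixed homo/hetero channel
  populations, all reproducible from a single seed with ground truth
  attached;
- **CLI** — `simulate`, `make-synthetic`, `analyze`, `reproduce`.

## CLI

```sh
# noise-free model currents for the default 19-step gating protocol
kvgating simulate --model heterotetramer --out out/

# noisy synthetic recording (seed-reproducible, ground-truth sidecar)
kvgating make-synthetic --model homotetramer --seed 7 --out out/

# Q-V + Boltzmann fits, tau-V, crossings from an episodic trace file
kvgating analyze out/synthetic_gating.tsv --out out/

# round-trip the published fit parameters; exit code 2 on failure
kvgating reproduce --out out/
```

All commands accept `--config <json>` (see `RunConfig` in
`kvgating/cli.py`); outputs carry a config hash and provenance
sidecars. Episodic traces are tab-delimited text with a `#`-commented
header (time column plus one current column per episode).

## Calibration

The measured rate constants of the original study are not available in
machine-readable form, so subunit kinetics are calibrated from the
published Boltzmann/τ_w parameters
(`kvgating.kinetics.calibrate_from_boltzmann`): total per-subunit
charge `z = V_T/slope` split symmetrically between the forward and
backward exponents (which places the τ–V bell maximum at the subunit
midpoint), midpoint pinned to the published Q½, and the absolute rate
scale fixed by one τ reference point. `kvgating.presets` holds the
published targets and ready-made assemblies.

## Known limitations

- **Apparent-charge discrepancy.** The published per-subunit charges
  (3.8, 1.8, 3.0 e₀) are ≈1.48× smaller than `z = k_B·T/(slope·e₀)`
  evaluated at room temperature from the published slopes (5.59, 2.73,
  4.43 e₀). The package implements the printed formula and does not
  rescale; `presets.APPARENT_CHARGE_HOMO` keeps the printed value for
  the ×4 total-charge arithmetic.
- **τ–V bell positions.** With the symmetric charge split the
  hyperpolarized τ–V bell of the heterotetramer peaks at the distinct
  subunit's midpoint (≈−90 mV) rather than at the −70 mV reported for
  the measured curve.
- **Cole–Moore shift ordering.** With a single closed state per
  subunit and Q–V-calibrated kinetics, both prepulses (−140/−60 mV)
  leave the common sensors essentially fully deactivated, so the
  simulated homotetramer shows a near-zero shift and the
  experimentally observed ordering (homo ≫ hetero > 0) is not
  reproduced. The corresponding acceptance test is left failing by
  design rather than weakened.
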