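# dmsbox

A zero-dimensional box model of the marine DMSP/DMS cycle for a shallow,
permanently mixed coastal water column, with explicit bacterial
transformations and air-sea gas exchange.

The model tracks three sulfur pools — particulate DMSP per phytoplankton
functional type (diatoms `DA`, nanoflagellates `NF`, colonial haptophytes
`OP`), dissolved DMSP, and DMS — driven by a plankton carbon-flux forcing
series.  Processes:

* DMSP synthesis proportional to growth through fixed S:C quotas; losses
  through lysis, grazing and sedimentation;
* direct DMS production by algal DMSP-lyase on the lysed fraction;
* bacterial DMSPd uptake scaled by carbon uptake and substrate
  stoichiometry, partitioned into sulfur assimilation, demethylation and
  lyase cleavage to DMS (cleavage shuts off under sulfur limitation, with
  DMS uptake topping up the unmet demand);
* DMS losses to bacterial consumption, depth-averaged photooxidation and
  wind-driven emission (Schmidt-number-corrected transfer velocities, two
  k600 parameterizations);
* explicit Euler integration (15-minute default step) with a proportional
  flux limiter and an exact per-step sulfur ledger.

On top of the simulator the package provides:

* `dmsbox.forcing` — a synthetic annual forcing generator (Gaussian bloom
  pulses with exact discrete carbon closure, lagged bacterial response,
  autocorrelated winds), CSV IO and a validator;
* `dmsbox.budget` — annual areal sulfur budgets (mmolS m⁻² y⁻¹), closure
  diagnostics and percentage shares, also computable directly from
  published flux numbers;
* `dmsbox.empirical` — five published chlorophyll-based DMS predictors
  (broken-stick, mixed-layer, linear, and two community-index forms) and
  a comparison harness against the simulator;
* `dmsbox.experiments` — a 21-test sensitivity sweep over quotas, lyase
  yields, bacterial community ratios, wind and k600 choice.

## CLI

```sh
dmsbox synth-forcing --seed 1 --out runs/forcing      # synthetic year, CSV
dmsbox run --seed 1 --out runs/ref                    # trajectory + ledger + budget
dmsbox budget --from-printed fluxes.json --out shares.json
dmsbox sensitivity --tests builtin --out runs/sweep   # reference + 21 tests
dmsbox empirical --relationship lana --chl 0.5
dmsbox gas --u10 7 -t 12 --method yang
```

Every run directory gets a `manifest.json` (seed, config hash, package
version, timestamp); identical config + seed reproduce outputs exactly.
Exit codes: 0 success, 2 validation failure, 3 numerical failure.

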