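# woodyroot

A field-to-parameter pipeline for the root system architecture (RSA) of
woody perennials, built around the workflow used for young grafted
grapevine rootstocks: 3-D digitizer point files are parsed into typed
root-system trees, archived as RSML, summarized into architectural traits
and growth-model parameters, regrown with a stochastic lateral-growth
simulator, and evaluated hydraulically (standard uptake fractions and
whole-root-system conductance).

## The pipeline

```
digitizer .txt ──parse──▶ RootSystem ──▶ RSML archive
                             │
                             ├─▶ traits (lengths, counts, hulls, depth profile)
                             ├─▶ parameter estimation (lb, la, ln, θ, lmax, r)
                             ├─▶ growth simulation (regrown laterals)
                             └─▶ hydraulics (SUF, Krs, uptake-depth profile)
```

Root axes are typed: **0** stem, **1** static woody adventitious roots,
**2** first-order laterals that regrow after planting, **3** fine
laterals.  All geometry lives in a right-handed soil frame with `z = 0`
at the soil surface and coordinates in cm.

## Quick start

```bash
# generate a synthetic digitizer file plus its ground truth
woodyroot synth --genotype 101-14 --days 180 --seed 7 -o fixture/

# inspect the reconstructed topology
woodyroot parse fixture/digitized.txt

# architectural traits as JSON
woodyroot traits fixture/digitized.txt

# estimate branching/growth parameters
woodyroot estimate fixture/digitized.txt --age 180

# simulate lateral regrowth under a genotype parameter set
woodyroot simulate --genotype SO4 --days 180 --seed 1 -o sim.rsml

# hydraulic evaluation: Krs and the uptake-depth distribution
woodyroot suf sim.rsml

# or run the whole chain from one config
woodyroot run config.yaml -o out/
```

A minimal `config.yaml`:

```yaml
input: fixture/digitized.txt
genotype: "101-14"
age_days: 180
days: 180
seed: 1
```

`woodyroot run` writes `root_system.rsml`, `traits.json`,
`estimates.json`, `simulated.rsml`, `simulated_traits.json`, `suf.json`
and a `manifest.json` with SHA-256 hashes of every artefact.

## Library use

```python
import woodyroot as w

records, soil_ref = w.read_digitizer_file("plant.txt")
rs, deviations = w.build_root_system(records, soil_ref=soil_ref)

report = w.compute_traits(rs)
est = w.branching_parameters(rs)

state = w.initialize_static(rs, w.GENOTYPES["101-14"])
sim = w.simulate(state, days=180, seed=0)

sol = w.solve_suf_krs(sim.root_system, w.HydraulicParams())
layers, horizons = w.suf_profile(sol)
```

Three genotype parameter presets ship with the package (`101-14`, `SO4`,
`R110`); `load_params`/`dump_params` round-trip custom parameter sets
through YAML.

The shipped radial-conductivity defaults are an order-of-magnitude
placeholder table (radial conductivities are rarely measured alongside
architecture); override them via `HydraulicParams.from_yaml`.

See `docs/methods.md` for the model formulations and conventions.

## Tests

```bash
python -m pytest -q tests/
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
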