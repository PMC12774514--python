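# n2osource

Quantitative pipeline for apportioning euphotic-zone N₂O among microbial
sources and for quantifying substrate-specific (ammonium vs urea)
nitrification and N₂O production from ¹⁵N tracer incubations:

- **Keeling regression** of isotope signals (δ¹⁵N^bulk, δ¹⁸O, site
  preference) against 1/[N₂O], with a two-endmember atmospheric
  correction for surface exchange;
- **Bayesian four-source unmixing** (archaeal nitrification aN, bacterial
  nitrification bN, nitrifier denitrification nD, denitrification bD)
  with a closed-system Rayleigh term `μ·ln(r)` for partial N₂O reduction,
  jointly fitting all three signals by MCMC;
- **tracer rate equations** — nitrification rate, N₂O production rate
  (N-atom basis from ⁴⁵/⁴⁶N₂O), hybrid fraction, N₂O yield — with
  detection-limit censoring, trapezoidal depth integration, and urea
  substrate-contribution ratios;
- **paired acidification statistics** — percent change, median/IQR,
  percentile-bootstrap CIs for medians, leave-one-station-out checks;
- **headspace solubility conversion** (Weiss & Price 1980 N₂O fit);
- **synthetic data generators** with serialized ground truth so every
  stage has a recovery test without external data.

## CLI

All stages are subcommands of a single entry point:

```sh
n2osource simulate profile --seed 1 --out demo/          # + truth.json
n2osource keeling --profiles demo/profiles.csv --signal sp \
    --layer subsurface --out demo/keeling.json
n2osource unmix --obs corrected.csv --seed 42 --out posterior.csv
n2osource simulate paired --seed 2 --out demo/
n2osource rates --incubations demo/incubations.csv --out demo/rates.csv
n2osource integrate --rates demo/rates.csv --top 0 --bottom 100 \
    --out demo/integrated.json
n2osource respond --rates demo/rates.csv --resamples 10000 --seed 7 \
    --out demo/response.json
n2osource run --seed 5 --out demo_run/                    # end to end
```

`n2osource run` chains simulate → keeling → unmix → rates → integrate →
respond on the default synthetic scenario and writes a `summary.json`
with the headline quantities (mean ± sd of the aN fraction, urea
contribution fractions for nitrification and N₂O production, and
acidification medians with bootstrap CIs). Runs are deterministic for a
fixed seed.

## File schemas

All I/O is plain CSV/JSON (UTF-8, comma separators, `.` decimal).

`profiles.csv` — one row per station/depth:
`station_id, depth, layer {surface|subsurface}, c_n2o [nmol L⁻¹],
d15n_bulk, d18o, d15n_alpha, d15n_beta, sp [‰],
sigma_d15n_bulk, sigma_d18o, sigma_sp` (sigmas default 0.2/0.5/1.0 ‰).
`sp` may be omitted when α/β are present (filled as α − β).

`incubations.csv` — one row per bottle:
`station_id, depth, substrate {ammonium|urea}, treatment
{control|acidified}, replicate, f_substrate (¹⁵N atom fraction of the
substrate N pool, (0,1]), delta_t [h], c0_nox15, ct_nox15 [nmol N L⁻¹],
dc45, dc46 [pmol L⁻¹]`.

`rates.csv` — per-bottle derived rates:
`..., r_nitr [nmol N L⁻¹ d⁻¹], r_n2o [pmol N L⁻¹ d⁻¹, N-atom basis],
yield_n2o, below_lod_nitr, below_lod_n2o`.

Conventions worth noting:

- rates at or **≤** the detection limit (defaults 0.015 nmol N L⁻¹ d⁻¹
  and 0.25 pmol L⁻¹ d⁻¹) are flagged, never dropped or clipped;
  negative tracer differences propagate to (flagged) negative rates;
- the N₂O production rate counts labeled N **atoms** (one per ⁴⁵N₂O,
  two per ⁴⁶N₂O) and applies the hour→day factor, so both rate
  equations are dimensionally per day; the yield converts the N₂O rate
  to nmol N before forming `R_N₂O / (R_N₂O + R_nitr)`;
- the Rayleigh μ convention: the forward model adds `μ·ln(r)`; μ must be
  negative for reduction to enrich the residual pool (see
  `src/n2osource/data/endmembers.yaml`, which ships editable
  literature-default endmembers);
- Keeling significance gate: `microbial_dominated` iff p < α (ties go to
  `atmosphere_dominated`);
- quantiles use linear interpolation; the bootstrap is the percentile
  flavor.

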