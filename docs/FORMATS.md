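# File formats

All tables are comma-separated text with a header row; units are embedded
in column names. Numbers are written with 17 significant digits and parsed
locale-independently, so tables round trip at full double precision.

## Decay curves (`decay_curves.csv`)

One row per (site, channel, temperature, t_rel) point.

| column         | meaning                                         |
|----------------|-------------------------------------------------|
| site           | site identifier (free text)                     |
| channel        | T1H, T1rhoH, T2H, T1C, or T2C                   |
| temperature_C  | sample temperature, °C                          |
| t_rel_s        | relaxation period, s                            |
| amplitude      | signal amplitude, arbitrary units               |
| sigma          | amplitude uncertainty (RMS noise), same units   |
| mode           | peak-height or peak-area                        |

## Observation sets (`observations.csv`)

One row per measured relaxation rate entering a grid fit.

| column       | meaning                                            |
|--------------|----------------------------------------------------|
| site         | site identifier                                    |
| site_class   | methine-CH or methylene-HH+HC                      |
| temperature_C| °C                                                 |
| channel      | observable (restricted by site class)              |
| rate_per_s   | 1/T, s⁻¹                                           |
| sigma_per_s  | uncertainty on the rate, s⁻¹                       |

## Fit results (`fit_results.csv`)

site, channel, temperature_C, model (single-offset | single | stretched),
a, b, T_s, beta_stretch, redchi, T_stderr_s.

## Motion parameters (`motion_parameters.csv`)

Per-site posterior table: site, temperature_C, tau_c1_ns, tau_c1_sd_ns,
tau_c2_ns, tau_c2_sd_ns, a1, a1_sd, min_chi2. Means and SDs are the
probability-weighted grid summaries.

## Echo curves (`--out` of simulate-echo)

n (rotor periods per half echo), total_time_s (2n/ν_r), amplitude.

## Run configuration (YAML)

Sections and keys (all optional; shipped defaults fill the rest):

```yaml
context: {proton_mhz: 599.1, omega1_hz: 1.0e4}   # or b0_tesla
grid:    {n1: 100, n2: 100, tau1_ns: [10, 500], tau2_ns: [0.1, 9]}
site:    {class: methylene-HH+HC, r_hc_nm: 0.110, r_hh_nm: 0.176}
plan:    {a1: 0.25, tau_c1_ns: 100, tau_c2_ns: 1,
          amplitude_noise: 0.02, rate_noise: 0.05, seed: 0}
echo:    {nu_r_khz: 1.2, steps_per_period: 200, orientations: 144}
```

## Run log (`runlog.json`)

Written next to every artifact set: SHA-256 hash of the effective
configuration, the configuration itself, the seed, the package version,
and the wall-clock time — enough to replay deterministic stages exactly.
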