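# pykrm

Kirchhoff Ray Mode (KRM) backscatter modelling of swimbladdered fish, with
the surrounding fisheries-acoustics toolchain: swimbladder morphometry from
digitized radiograph station tables, tilt-angle-averaged target strength,
TS–length regression, and the relative frequency response used to tell
species apart with multifrequency echosounders.

Acoustic surveys convert volume backscattering strength into biomass through
the species-specific target strength, `TS = 10 log10(σ_bs)` dB re 1 m² with
`σ_bs = |L|²` the backscattering cross-section. For most fish the gas-filled
swimbladder dominates the echo. The KRM approximates a fish as stacks of
short gas-filled (swimbladder) and fluid-filled (body) cylinders and sums
their Kirchhoff-ray echoes coherently — accurate near dorsal incidence at a
tiny fraction of the cost of full-wave solvers, which makes it practical to
compute `TS(f, θ)` over whole frequency bands and orientation distributions,
fit `TS = m log10(L) + b` and `TS = 20 log10(L) + b20` against total length,
and derive the frequency-ratio fingerprint `r(f) = σ(f)/σ(38 kHz)`.

The package is aimed at fisheries acousticians who have (or simulate)
digitized fish shapes. Since the study species' radiographs are not publicly
deposited, a seeded synthetic generator reproduces the two species'
swimbladder morphologies (an elongated pear-shaped bladder for the
Mediterranean horse mackerel, a near-spherical one for the Atlantic chub
mackerel) with published mean dimensions and length scaling, so every stage
is runnable and testable end to end. Exact references — the fluid-sphere
modal series and a sound-soft prolate-spheroid spheroidal-wave series built
to remain accurate where `scipy`'s spheroidal functions break down — serve
as independent oracles for the scattering core.

## Worked example

```python
import numpy as np
from pykrm import (MaterialSet, T_MEDITERRANEUS, TiltDistribution,
                   generate_fish, krm_grid, measure_morphometrics,
                   tilt_averaged_sigma)

fish = generate_fish(T_MEDITERRANEUS, tl_cm=15.4, seed=0)
print(measure_morphometrics(fish).as_dict())

grid = krm_grid(fish, MaterialSet(),
                f_hz=[38e3, 70e3, 120e3, 200e3],
                theta_deg=np.arange(65.0, 116.0, 1.0))
print("TS(38 kHz, broadside):", round(grid.ts_at(38e3, 90.0), 2), "dB")

sbar = tilt_averaged_sigma(grid, TiltDistribution(88, 13))
print("tilt-averaged TS(38 kHz):", round(10 * np.log10(sbar[0]), 2), "dB")
```

prints

```
{'sbl_mm': 50.25..., 'sbh_mm': 3.978..., 'sbw_mm': 4.922..., 'sb_theta_deg': 11.16...,
 'dorsal_area_mm2': 126.85..., 'volume_mm3': 515.38...}
TS(38 kHz, broadside): -41.64 dB
tilt-averaged TS(38 kHz): -43.27 dB
```

— a 15.4 cm specimen whose generated bladder (50.3 × 4.0 × 4.9 mm, inclined
11.2° to the body axis) echoes at −41.6 dB broadside at 38 kHz, dropping
1.6 dB once averaged over a natural swimming-orientation spread of 88° ± 13°.

The full chain — per-fish morphometrics, KRM grids, tilt averaging over the
five standard orientation distributions, the TS–length table and the RFI
table — runs in one call or from the shell:

```python
from pykrm import RunConfig, run_pipeline
result = run_pipeline(RunConfig(seed=1),
                      species_template="T. mediterraneus", n_fish=25)
print(result.ts_length)   # m, b, s.e., r2, b20 per tilt distribution
```

```sh
pykrm run --species-template "T. mediterraneus" --n-fish 25 --seed 1 --out-dir out/
pykrm benchmark --oracle my_fem_spectrum.tsv   # KRM vs an external full-wave TS(f)
```

For the 25-fish synthetic cohort above, the fixed-slope conversion parameter
comes out at `b20 = −67.55 dB` (s.e. 0.16) for the 88° ± 13° orientation
distribution, and the tilt-averaged frequency-response ratios fall from 1.0
at 38 kHz to 0.83 / 0.70 / 0.61 at 70 / 120 / 200 kHz.

## Layout

| module | contents |
| --- | --- |
| `pykrm.shapes` | station-table geometry, resampling, morphometrics |
| `pykrm.krm` | the KRM engine, backscatter grids, slice sensitivity, spectrum comparison |
| `pykrm.oracles` / `pykrm.spheroidal` | exact sphere and spheroid references |
| `pykrm.analysis` | tilt averaging, TS–length fits, RFI, allometry, species comparison |
| `pykrm.synthetic` | species templates, cohort generator, benchmark spheroids |
| `pykrm.pipeline` / `pykrm.cli` | configuration, end-to-end runs, `pykrm` subcommands |

Model equations, parameter defaults, the synthetic-data assumptions and
known limitations are documented in `docs/methods.md`.
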