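# kowkit

Reliable determination of octanol–water partition coefficients
(K_OW) and distribution coefficients (D_OW) of ionizable and neutral
solutes from biphasic (shake-flask) partition measurements — together
with a forward simulator of the solute/octanol/water
ionization–partition equilibrium that validates the data-reduction
methods by parameter recovery, and screening statistics over curated
literature values.

## Why

For a neutral solute the measured ratio log P = log10(c_org/c_aq)
extrapolates benignly to its zero-concentration limit, log K_OW. For
the weak acids and bases that make up most drug-like molecules, the
experiment instead yields the distribution coefficient

    log D = log10[(c_org,neutral + c_org,charged) /
                  (c_aq,neutral + c_aq,charged)],

which collapses at low concentration as the solute ionizes.
Extrapolating log D against concentration is therefore ill-conditioned,
and published K_OW values for the same ionizable drug scatter over
several orders of magnitude (the packaged literature table shows a
spread of 4.5 log units for glibenclamide). The package implements two
well-conditioned reductions:

* **Method 1** — fit log D against the measured aqueous pH and read the
  line off at pH 7 (the aqueous pH at zero solute concentration); the
  result is log D_OW, converted to log K_OW with the ionization
  correction `log P = log D + log10(1 + 10^(pH−pKa))` (acids; exponent
  `pKa−pH` for bases, conjugate-acid pKa convention).
* **Method 2** — convert each log D to log P with that measurement's
  own pH, then take the zero-concentration intercept of log P vs
  overall concentration.

Both are exact in the dilute, strongly ionized regime, and their
disagreement at higher concentrations is itself a useful diagnostic,
which the tool reports.

## Worked example

```python
from kowkit import (BiphasicSystem, NoiseModel, Solute,
                    fit_method1, fit_method2, simulate_series)

naproxen = Solute("naproxen", "acid", pKa=4.18)
system = BiphasicSystem(volume_org=0.25, volume_aq=0.75,
                        P_neutral_0=10**3.34)   # true log K_OW = 3.34
series = simulate_series(naproxen, system,
                         c_total_grid=(1e-9, 1e-8, 1e-7, 1e-6),
                         noise=NoiseModel(rel_conc_sigma=0.05,
                                          ph_sigma=0.02, seed=7))
m1, m2 = fit_method1(series), fit_method2(series)
print(f"method 1: log K_OW = {m1.log_value:.3f} +/- {m1.std_error:.3f} "
      f"(log D_OW at pH 7 = {m1.intermediate_logDow:.3f}, r^2 = {m1.r_squared:.4f})")
print(f"method 2: log K_OW = {m2.log_value:.3f} +/- {m2.std_error:.3f}")
print(f"method disagreement: {abs(m1.log_value - m2.log_value):.3f}")
```

prints

```
method 1: log K_OW = 3.314 +/- 0.009 (log D_OW at pH 7 = 0.494, r^2 = 0.9976)
method 2: log K_OW = 3.314 +/- 0.008
method disagreement: 0.000
```

Both reductions recover the configured log K_OW = 3.34 within the
uncertainty implied by 5 % concentration noise on four measurements;
the intermediate log D_OW = 0.494 is the distribution coefficient at
pH 7, i.e. of the fully ionized solute, 2.8 log units below log K_OW.

## Command line

```
kowkit simulate --config scenario.yaml --seed 1 --out meas.csv
kowkit reduce meas.csv --method all --out result.json
kowkit convert logd_table.csv        # adds an ionization-corrected log_p column
kowkit screen                        # literature spread statistics
```

`kowkit screen` recomputes the per-substance spread of published
values from the curated table (mean 1.09 log units for nonionizable
drugs vs 1.95 for ionizable ones, topped by glibenclamide's 4.50) and
the method-1/method-2 disagreement of the four-drug comparison
(naproxen 0.14, ibuprofen 0.11, lidocaine 1.40 log units).

Logs go to stderr, data to stdout or files; every output embeds the
tool version, a config hash, and the seed. Exit codes: 0 success,
2 validation error, 3 solver/fit failure.

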