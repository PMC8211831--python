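# ventcal

Indirect calorimetry for mechanically ventilated subjects, built around a
directly measured molecular ratio **R = VI/VE** of inhalation to exhalation.

The ratio is obtained by timing a constant-rate pump that first collects
exhaled gas into a bag (duration *te*) and then empties it (*ti*): with bag
temperature and pressure equilibrated to ambient, `R = te/ti`. Unlike the
Haldane transformation (`VI/VE = (1 − FEO2 − FECO2)/(1 − FIO2)`), this works
at FIO2 = 1.0, where the Haldane denominator vanishes.

## What's in the package

| module | purpose |
| --- | --- |
| `ventcal.psychrometry` | saturation vapor pressure (Arden Buck 1981), water mole fraction, humid↔dry molar factors, dew point |
| `ventcal.gas_corrections` | CO2/O2 cross-sensitivity fix, calibration-vs-circuit pressure standardization, wet→dry fractions, pre/post FIO2 drift interpolation, 60-s averaging |
| `ventcal.molar_ratio` | bag timings → R, humid→dry ratio conversion, test-lung QC, the packaged 24-row reference table |
| `ventcal.metabolism` | VO2 = (R·FIO2 − FEO2)·VE, VCO2, RQ, STPD conversion, per-kg normalization, Haldane comparison, full pipeline |
| `ventcal.error_budget` | first-order (quadrature) and Monte-Carlo propagation of R and O2 sensor errors into VO2 |
| `ventcal.simulator` | mass-balance forward model of a ventilated subject with non-CO2-producing O2 sinks and an N2-imbalance term; noise injection; cohort generation |
| `ventcal.analysis` | group summaries (population SD), exact Mann–Whitney U (full permutation null), reference-table reproduction report |
| `ventcal.cli` | `ventcal` command-line interface |

## CLI

```bash
ventcal table1                     # golden reproduction report (add --json)
ventcal dry-ratio in.csv -o out.csv        # humid→dry ratios + QC flags
ventcal metabolism --r 1.0074 --fio2 0.3 --feo2 0.26 --feco2 0.04 \
    --ve 400 --mass-kg 0.45                # VO2/VCO2/RQ from dry fractions
ventcal --seed 3 simulate -o cohort.csv    # synthetic 2×2 cohort
ventcal error-budget --fio2-grid 0.3,0.6,1.0 --extraction 0.048
ventcal stats --x 1,2,3 --y 4,5,6          # exact Mann–Whitney U
```

Exit codes: 0 success, 2 validation failure, 3 QC failure.

The ratio CSV schema is
`group,r_test_lung,r_humid,pressure_hpa,temp_c,rh_pct[,r_dry]` (RH in
percent); outputs add `r_dry_computed,qc_pass`. The simulator emits the same
schema extended with `true_vo2,true_vco2,true_rq,seed`.

## Notes on fidelity

* The humid→dry correction reproduces the printed dry-R column of blocks
  (a)/(b) of the reference table to ≤ 5×10⁻⁵; blocks (c)/(d) deviate by up
  to ~1.6×10⁻³ from any standard vapor-pressure formula applied to their own
  printed inputs (possibly an additional volatile-agent correction in the
  original data reduction). They are treated as given data, not as a
  correction oracle.
* One printed summary SD (the volatile-anesthesia group) computes to 0.0024
  with either SD denominator while 0.0023 is printed; it is reported as
  computed.
* Group summaries use the population SD (n denominator), which reproduces
  the other three printed ± values exactly at 4 decimals.
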