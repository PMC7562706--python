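# carrieraif

Non-radiometric arterial input functions (AIFs) for short-lived PET
radiotracers, computed from LC-MS/MS quantification of the tracer's
non-radioactive carrier instead of radioactivity counting.

A carbon-11 tracer dose is always dominated (in mass) by its stable
isotopologues.  Measuring the dose's molar activity (`A_m`, GBq/umol) from
the isotopologue peak-area pattern, and then the carrier concentration in
arterial plasma over the scan, yields a radioactivity input function
`AIF(t) = C_carrier(t) * A_m` with no gamma counting, no radiometabolite
chromatography under time pressure, and no detector-geometry systematics.

## What is implemented

| module                    | contents |
| ------------------------- | -------- |
| `carrieraif.nuclide`      | nuclide constants (`A_m* = ln2/t_half * N_A` computed, never hard-coded), decay correction, first-order natural M+1 isotopologue ratios |
| `carrieraif.molar_activity` | `A_m` from two- or three-channel isotopologue areas, carrier/radioactivity interconversion, enrichment-vs-`A_m` line fit |
| `carrieraif.plasma`       | internal-standard calibration (unweighted OLS), plasma carrier quantification, isotope-skew correction `(100+x)/(100+y)*c` |
| `carrieraif.aif`          | pM -> kBq/mL conversion, radiometric AIF from gamma counts x parent fraction, systematic-difference correction (geometric-mean factor), trapezoid AUC, VAR / Pearson / paired t / single-measures ICC |
| `carrieraif.synthetic`    | full synthetic-study generator with retained ground truth: isotope co-production, carrier contamination, 23-point arterial schedule, multi-exponential clearance, declining parent fraction, ~1.32x gamma bias, lognormal noise |
| `carrieraif.pipeline` / `carrieraif.cli` | CSV-contract orchestration, provenance records, command-line interface |

## CLI

```sh
# generate a synthetic 8-subject study (CSV bundle + ground-truth sidecar)
carrieraif simulate --seed 1 --out data/

# per-preparation molar activity from dose isotopologue areas
carrieraif am --dose-csv data/dose_areas.csv --out results/

# plasma carrier concentrations (calibration + skew correction)
carrieraif quantify --plasma-csv data/plasma.csv \
    --calibration-csv data/calibration.csv \
    --am-csv results/am_report.csv --out results/

# three AIFs per subject + method comparison
carrieraif aif --quant-csv results/quantified_plasma.csv \
    --gamma-csv data/gamma.csv --pf-csv data/parent_fraction.csv \
    --am-csv results/am_report.csv --vials-csv data/dose_vials.csv \
    --out results/

# everything end to end, with a ground-truth recovery table
carrieraif report --seed 1 --out results/
```

Configuration is a YAML file (`--config`) validated against
`carrieraif.config.StudyConfig`; all keys have working defaults.  Example:

```yaml
seed: 1
natural_ratio_pct: 9.16
constants:
  half_life_min: 20.4
simulation:
  n_subjects: 8
  gamma_bias_mean: 1.32
```

## Notes on conventions

* `A_m` is stored in GBq/umol (ceiling: the carrier-free value, ~341,300).
* Unit algebra used throughout: `pmol x GBq/umol = kBq` and
  `pM x GBq/umol = Bq/mL`.
* Decay corrections reference end of synthesis; measurement records carry
  explicit second offsets.
* The radioactive-species signal is inflated by the *reference* compound's
  natural M+1 ratio (enrichment sits at the label site, which is occupied
  by the radionuclide in those molecules); this is configurable.
* The systematic gamma/LC-MS/MS factor is the geometric mean of paired
  ratios, estimated per preparation from dose-vial pairs by default
  (`correction_source: aif_pairs` self-calibrates from the curves instead).
* Single-measures ICC defaults to the one-way random-effects form, with the
  two-way absolute-agreement form available (`icc_model`).
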