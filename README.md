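# nmlab

1D NMR spectral processing, metabolomics pre-processing, and 13C-tracer
multiplet/isotopomer analysis in plain Python.

The package covers three workflows:

1. **1D spectrum processing** — read Bruker experiment directories
   (int32/float64, both endiannesses), exponential apodization, zero-filling,
   Fourier transform with digital-filter group-delay compensation,
   zero/first-order phasing, automatic referencing (TMSP / water / manual
   anchor), post-acquisition water suppression (FID polynomial fit,
   Gaussian/sine convolution), and cubic-spline baseline correction with
   linear fill across anchor gaps.
2. **Automatic phase correction** — a per-spectrum algorithm (normalized-L1
   objective; penalized derivative entropy also available) and a
   reference-based algorithm for series: starting from a corrected reference
   spectrum's phases, it minimizes the absolute deviation and level
   difference of the signal-free baseline regions at the spectrum edges
   (> 10.0 ppm and < -0.5 ppm) with Powell's conjugate-direction method.
3. **Series pre-processing and tracer analysis** — exclude regions,
   correlation-based segmental alignment, noise filtering, bucketing,
   TSA/PQN normalization, glog variance stabilization, MetaboAnalyst CSV and
   Excel export; HSQC multiplet models built from carbon-carbon scalar
   couplings (`.mlinfo` text library), automatic peak picking, Lorentzian
   line-shape fitting with an R² quality flag, and constrained least-squares
   estimation of isotopomer distributions from multiplet fractions combined
   with GC-MS mass-isotopologue data.

All test inputs are generated by the seeded `nmlab.synthetic` module —
no measured data are required.

## CLI

```sh
nmlab make-fixtures --out fixtures --seed 1     # synthetic fixture tree
nmlab process    --config process.yml           # Bruker -> processed dataset
nmlab preprocess --config preprocess.yml        # pipeline + CSV/Excel export
nmlab tracer     --config fixtures/tracer_config.yml
nmlab autophase1d --dataset ds.nmlab --index 0
nmlab autophase1d-all-bl --dataset ds.nmlab --ref-index 0
```

`process` reads the experiment directories listed in the config, applies
line broadening / zero-fill / FT, phases the first spectrum with the
per-spectrum algorithm and the remaining spectra with the reference-baseline
algorithm, and saves a native dataset (zip container, versioned JSON
manifest + arrays). Exit codes: 0 success, 1 runtime failure, 2
config/usage error.

Example `process.yml`:

```yaml
inputs: [fixtures/bruker/exp1, fixtures/bruker/exp2]
zero_fill: 131072
line_broadening_hz: 0.3
autophase: true
output: ds.nmlab
```

Example `preprocess.yml`:

```yaml
dataset: ds.nmlab
out_dir: out
options:
  exclude: [[4.5, 5.0]]
  align_segments: [[1.3, 1.7, 0, 50]]   # low, high, ref index, max shift
  noise_region: [9.5, 10.3]
  noise_factor: 4.0
  bucket_ppm: 0.02
  normalization: pqn
  glog_lambda: 1.0e-4
  export: metaboanalyst_csv
```

## Metabolite library

`.mlinfo` files are line-oriented text (see `src/nmlab/library/`):

```
metabolite: lactate
carbons: 3
carbon: 1 - 183.3        # index, 1H ppm ('-' = no attached proton), 13C ppm
carbon: 2 4.10 71.3
carbon: 3 1.31 22.7
jcc: 2 3 37.1            # one-bond carbon-carbon coupling in Hz
```

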