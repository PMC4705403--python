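# hcrquant

Quantification and inference for **host-cell reactivation reporter assays**:
measuring how well cells recover transcription from a reporter vector carrying a
single site-specific DNA lesion.

In these assays a damage-carrying reporter (RFP) and an undamaged transfection
control (GFP) are co-expressed; recovery of RFP expression over time reads out
DNA repair, and errors in the RFP transcripts read out transcriptional
mutagenesis (erroneous lesion bypass by RNA polymerase II). `hcrquant`
implements the full quantification chain:

- **Cy0 qPCR quantification** — each amplification curve is fit with a Richards
  sigmoid `F(x) = Fmax / (1 + exp(-(x-c)/b))^d`; **Cy0** is the cycle at which
  the tangent at the curve's inflection crosses zero fluorescence (for the
  Richards family, `Cy0 = c + b·ln d − b(1 + 1/d)`). Per-reaction efficiency is
  `Eff = 2^m` with `m` the slope of log₂ fluorescence over the five cycles
  centred on Cy0, averaged per amplicon per plate (LinRegPCR-style), and
  relative expression is `Eff^(−Cy0)`.
- **Combination-ratio normalization** — GFP expression follows a gamma
  distribution with shape < 2, so 1/GFP is heavy-tailed and simple RFP/GFP
  ratios misbehave at small n. For every unordered pair of measurements the
  ratio `(R_i + R_j)/(G_i + G_j)` is formed instead (pair sums have gamma shape
  > 2), and time courses are scaled so 100% is the undamaged control's maximum.
- **SMCV contrast statistics** — effects are measured by the standardized mean
  of a contrast variable, `λ̂ = Σcᵢ·Ȳᵢ / √(Σcᵢ²·sᵢ)` (sᵢ the group variance),
  converted to the c⁺-probability `Φ(λ̂)` and a one-sided p-value for the null
  "SMCV ≤ 0"; p < 0.050 (strict) is called significant.
- **Flow-cytometry gating** — spillover compensation by matrix inversion,
  per-event `ln(RFP/GFP)` normalization, and a two-component normal mixture
  (EM, k-means initialization, seeded restarts) that isolates the
  doxycycline-induced population; conditions are compared as percent of control
  with one-way ANOVA and linear contrasts.
- **Transcript-error tallying** — amplicon reads are aligned to the expected
  transcript with a banded affine-gap global aligner and classified at the
  lesion-opposite position (match / misincorporation / deletion / insertion);
  classes are reported when their frequency is ≥ 10× the 0.1% background
  misincorporation rate.
- **Synthetic-data generators** for all four input kinds, with ground truth,
  so the entire pipeline is testable without external data.

## Worked example

Simulate an expression experiment for a repair-deficient line in which a lesion
suppresses RFP to 5% of control at 6 h and 12% at 18 h, then normalize, scale
and test the 18 h lesion-vs-control contrast:

```python
from hcrquant.pipeline import RunConfig, run_mrna_pipeline

block = {
    "simulate": {
        "cell_lines": ["XPA"], "vectors": ["control", "BaP"],
        "time_points_h": [6.0, 18.0], "n_replicates": 6,
        "effects": [["XPA", "BaP", 6.0, 0.05], ["XPA", "BaP", 18.0, 0.12]],
    },
    "contrasts": [{
        "name": "BaP_vs_control_18h", "coefficients": [1.0, -1.0],
        "groups": [{"cell_line": "XPA", "vector": "control", "time_h": 18.0},
                   {"cell_line": "XPA", "vector": "BaP", "time_h": 18.0}],
    }],
}
run_mrna_pipeline(RunConfig(seed=7, out_dir="example_out", mrna=block))
```

`example_out/timecourses.csv` then holds the scaled time courses:

```
cell_line  vector  time_h   mean_pct       se  n
      XPA     BaP     6.0   5.189464 0.177725  6
      XPA     BaP    18.0  12.315464 0.842568  6
      XPA control     6.0  98.054259 3.398171  6
      XPA control    18.0 100.000000 4.359575  6
```

The control series peaks at exactly 100% (it defines the scale), and the
lesion-carrying vector recovers to ~12% of control at 18 h, close to the
simulated truth. `example_out/contrasts.csv` holds the contrast test:

```
          contrast     smcv  cplus            p  significant
BaP_vs_control_18h 8.061949    1.0 4.201030e-87  True
```

An SMCV of ~8 means the contrast (control minus lesion) is eight contrast-SDs
above zero — overwhelming evidence that the lesion suppresses expression.

The same config file drives the command line:

```sh
hcrquant run-all --config config.json     # every configured stage
hcrquant quantify --plate plate.csv --out quant.csv   # one qPCR plate
```

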