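# ivtkit

A Python toolkit for the quantitative assays used to characterise the
immunogenicity of in vitro transcribed (IVT) RNA. T7 polymerase products
carry a 5′-triphosphate and are contaminated to varying degrees by
double-stranded RNA byproducts; both are agonists of the RIG-I / type I
interferon pathway. Comparing RNA variants (for example transcripts
initiating with 5′-pppA versus 5′-pppG) therefore requires a pipeline of
several measurements: RNA structure by chemical probing, interferon
induction by reporter-cell dose-response, dsRNA content by quantitative dot
blot, virus protection by endpoint titration, and reporter activation by
image cytometry. `ivtkit` implements each of these analyses as a tested,
reusable library with a thin command-line layer, together with seeded
synthetic-data generators that make every stage verifiable against known
ground truth.

## What it computes

**SHAPE-MaP reactivity** (`ivtkit.shape`). From per-position mutation and
coverage counts of NAI-probed and DMSO-control channels: mutation rates
m/c, raw reactivity = rate(NAI) − rate(DMSO), and normalized reactivity =
raw / (1.5·(Q₃ − Q₁)) with quartiles taken over the raw reactivities of the
RNA. Positions are reported only where coverage strictly exceeds 10 000×
in every contributing channel. Profiles can be exported as SHAPE
constraint files for structure-prediction tools.

**Differential reactivity** (`ivtkit.diffreact`). Position-wise comparison
of two RNAs: normalized reactivities are square-root transformed, a
two-group linear model is fitted per position, and variances are shrunk
with an empirical-Bayes moderated t-test,
s̃²_g = (d₀s₀² + d·s²_g)/(d₀ + d), with the prior (d₀, s₀²) estimated by
moment matching on log s² and the statistic referred to t with d + d₀
degrees of freedom. Significance is a fixed strict P < 0.001. The
implementation reproduces Bioconductor limma to machine precision (checked
in the test suite via Rscript).

**Dose-response / apparent K_d** (`ivtkit.dose_response`). Blank-corrected
reporter optical densities are fitted to the four-parameter logistic

    OD = Bottom + (Top − Bottom) / (1 + (K_d / c)^Slope),  Bottom ≡ 0,

with ROUT outlier removal (robust Lorentzian fit, RSDR scale, FDR-style
flagging at Q = 1%). Two RNA variants are compared by refitting with a
shared K_d and evaluating AICc = N·ln(SS/N) + 2K + 2K(K+1)/(N−K−1); the
evidence for distinct K_d values is Akaike's probability
1 − (e^(ΔAICc/2) + 1)^(−1). A free-Bottom 4PL standard curve of
recombinant IFN-β converts sample ODs into semiquantitative IFN
concentrations with censoring at the quantification limits.

**Endpoint titration** (`ivtkit.titer`). Spearman–Kärber log₁₀ CCID50 from
dilution-series infection matrices, with explicit censoring when the 50%
endpoint is not bracketed.

**Dot-blot densitometry** (`ivtkit.blot`). Intensity vs log₁₀(amount)
standard curves (Φ6 dsRNA series 500–16 pg by default), interpolation of
unknown dsRNA amounts, contamination fractions and group fold differences.

**Image cytometry** (`ivtkit.imaging`). Reporter-positive cell counts by
global threshold + 8-connected components, gated on occupied area within
150–800 μm² and mean intensity ≥ 400.

**Synthetic data** (`ivtkit.synthdata`). Seeded generators for every input
above, each paired with a ground-truth record for recovery testing.

## Worked example: comparing apparent K_d of two RNA variants

Simulate two dose-response datasets with a true 92-fold K_d difference
(K_d = 1.2 and 110 ng/ml, Top = 1, Slope = 1, noise SD 0.05, 8
concentrations from 0.1 to 1000 ng/ml in quadruplicate), written as a
plate CSV, then compare:

```
ivtkit kd-compare --plate plate.csv --group-a pppA --group-b pppG \
    --out comparison.json
```

`comparison.json` (abridged):

```json
{
  "kd_a": 1.14504,
  "kd_b": 115.869,
  "kd_ratio": 101.192,
  "delta_aicc": 111.465,
  "akaike_probability": 1.0,
  "prefers_separate": true,
  "n_points": 64, "k_separate": 6, "k_shared": 5
}
```

The separate fits recover the generating midpoints (1.145 vs 1.2 and 115.9
vs 110 ng/ml), the estimated ratio is 101 against a true 92, and sharing a
single K_d across both datasets is decisively rejected (ΔAICc ≈ 111, an
Akaike probability of essentially 1 that the potencies differ).

The same pattern works for every stage, e.g.

```
ivtkit simulate shape --seed 7 --length 80 --out-dir sim
ivtkit reactivity --counts sim/counts.tsv --out-dir profiles
ivtkit diffreact --group-a a_matrix.tsv --group-b b_matrix.tsv --out diff.tsv
ivtkit titer --table titer.tsv --out titer.json
ivtkit blot-quant --table blot.tsv --out blot.json
ivtkit count-cells --image field.tif --pixel-size 1.0 --out-prefix cells
```

Every run writes its resolved configuration next to its outputs, and a
fixed seed reproduces all output files byte-identically.

## Documentation

`docs/methods.md` describes the statistical models, the synthetic-data
generators and their deliberate simplifications, the numerical choices
(initialisation, bounds, tie-breaks, censoring rules), and known
limitations.
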