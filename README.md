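# corecruit

Genome-wide analysis of how a transcriptional co-repressor is targeted to
its sites.  The budding-yeast co-repressor complex Tup1–Ssn6 does not bind
DNA itself: it is tethered to individual promoters by sequence-specific
"recruiter" transcription factors.  Given genome-wide occupancy profiles
(ChIP-chip log2 IP/input ratios over intergenic regions) for the
co-repressor and a panel of candidate recruiters, this package answers:

* **Where is the co-repressor bound?**  Sliding-window peak calling on
  standardized replicate profiles with a Gaussian background null,
  Benjamini–Hochberg FDR, mock-IP filtering, and peak collapsing
  (`corecruit.peaks`).
* **Which cofactors co-occupy those sites?**  Target classification,
  recruiter-count binning, wild-type vs. deletion-strain comparison after
  cross-experiment scaling, and derepression tests
  (`corecruit.cooccupancy`).
* **Which factors look like new recruiters?**  A five-test composite
  screen — motif over-representation, sensitivity, specificity, and two
  top-quartile occupancy correlations — aggregated by average percentile
  rank (`corecruit.screen`).
* **How well do recruiter occupancies predict co-repressor occupancy?**
  A multiple linear regression, ŷ = β₀ + Σᵣ βᵣ·xᵣ, with Gaussian imputation
  of missing entries, univariate pre-screening, half-genome fits with
  repeated random-subsampling cross-validation, and nested-model
  comparison by partial F-test (`corecruit.regression`).

Because real array data is external, the package ships a first-class
synthetic-data generator (`corecruit.simulate`) that emulates the assumed
data-generating process — a two-component Gaussian mixture for recruiter
binding, a linear co-repressor model with calibrated residual noise,
deletion strains with tunable recruiter redundancy, downstream-gene
derepression, and region sequences with planted motifs — with full ground
truth, so every stage is testable end to end.  `corecruit.studies`
packages the reference in-silico experiments built on it.

## Worked example

Fit the occupancy model on a synthetic genome at the default study
conditions (6,000 intergenic regions, nine weighted recruiters, residual
noise calibrated so the generative model explains ≈43% of occupancy
variance genome-wide):

```python
import corecruit as cc
from corecruit import regression as rg

cfg = cc.GeneratorConfig(seed=42)            # 6,000 regions, 9 recruiters
regions, occ, truth = cc.generate_dataset(cfg)
model = rg.full_pipeline(occ.corepressor_values, occ.recruiter_ratios, seed=42)

print(f"recruiters retained: {model.included}")
for f in model.included:
    print(f"  {f:5s} beta = {model.weights[f]:+.3f}   "
          f"(planted {truth.planted_weights[f]:+.3f})")
print(f"intercept = {model.intercept:.3f}")
print(f"held-out R^2 = {model.r2_heldout:.3f}")
```

which prints:

```
recruiters retained: ['SUT1', 'NRG1', 'ROX1', 'SKO1', 'CUP9', 'YAP6', 'CIN5', 'PHD1', 'SKN7']
  SUT1  beta = +0.484   (planted +0.454)
  NRG1  beta = +0.332   (planted +0.348)
  ROX1  beta = +0.233   (planted +0.215)
  SKO1  beta = +0.171   (planted +0.198)
  CUP9  beta = +0.476   (planted +0.513)
  YAP6  beta = +0.657   (planted +0.706)
  CIN5  beta = +0.400   (planted +0.395)
  PHD1  beta = +0.191   (planted +0.190)
  SKN7  beta = +0.171   (planted +0.170)
intercept = 0.128
held-out R^2 = 0.397
```

Every planted weight is recovered within ±0.05 and no decoy survives the
screen; the held-out R² sits a little below the generative 0.43 because
5% of recruiter entries are missing and are filled by Gaussian imputation,
which attenuates the fit.

The same pipelines are available from the shell:

```bash
corecruit simulate --seed 42 --outdir data/
corecruit regress --data data/ --seed 42 --out model.tsv
corecruit screen --data data/ --out scorecard.tsv
corecruit cooccupancy --data data/ --out cooc/
```

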