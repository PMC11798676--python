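# sigattr

Sparse mutational-signature attribution driven by likelihood ratio tests,
with a negative-binomial synthetic spectrum generator, evaluation measures,
an NNLS baseline, and exhaustive attribution-ambiguity enumeration.

Given a tumor's mutational spectrum `D` (per-channel mutation counts in the
SBS96, DBS78, or ID83 classification) and a catalog `H` of signature
probability vectors, the attribution task is to find non-negative activities
`A` such that `D ≈ H × A`, using as few signatures as are statistically
necessary. The core algorithm works in two steps:

1. **Presence filtering** — for every offered signature, a leave-one-out
   likelihood ratio test (multinomial model, chi-square df = 1) asks whether
   removing it significantly worsens the best achievable fit; only
   signatures that are individually necessary survive.
2. **Greedy forward search** — starting from the empty set, repeatedly add
   the signature that raises the negative-binomial log-likelihood the most,
   stopping the first time the add-one LRT is non-significant.

## Library quick start

```python
import numpy as np
from sigattr import attribute, PasaConfig, load_matrix_tsv

spectra = load_matrix_tsv("spectra.tsv", role="spectra")       # k x n counts
catalog = load_matrix_tsv("catalog.tsv", role="signatures")    # k x g probs

result = attribute(spectra["sample1"], catalog, PasaConfig(alpha=0.01))
print(result.attribution.activities)      # {signature: activity}
print(result.reconstruction_cosine)
```

Matrix files are COSMIC-convention TSVs: first column holds mutation-type
row labels (any order; rows are canonicalized on load), remaining columns
are samples or signatures.

## CLI

A `sigattr` console script exposes five subcommands; every run writes a
JSON manifest (inputs, configuration, seed, version) next to its outputs.

```bash
sigattr attribute spectra.tsv catalog.tsv --alpha 0.01 --out run/
sigattr simulate params.json catalog.tsv -n 100 --seed 3 --out sim/
sigattr evaluate truth.tsv inferred.tsv universe.txt spectra.tsv --out eval/
sigattr enumerate spectra.tsv catalog.tsv --cosine-threshold 0.969 --out enum/
sigattr calibrate params.json catalog.tsv --target 0.969 --seed 1 --out cal/
```

`simulate` draws ground-truth activities from per-signature negative
binomials (presence with the observed prevalence, activity from NB(size,
mu) conditioned positive) and per-channel counts from negative binomials
centered on activity × channel probability. `calibrate` bisects a shared
channel dispersion until the median spectrum-to-reconstruction cosine hits
a target. `enumerate` NNLS-refits every nonempty signature subset and
counts distinct attributions (by positive-activity support) whose
reconstruction cosine clears a threshold, optionally also requiring every
activity to account for ≥ 3% of the sample's mutations.

Generator parameter files are JSON; see
`sigattr.toydata.toy_generator_params(...).to_json(path)` for the layout,
or fit your own from a cohort activity table with
`sigattr.synthetic_spectra.fit_generator_params`.

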