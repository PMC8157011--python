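# milkscreen

Untargeted FT-IR milk-spectra screening, cluster discovery and cluster
characterization — plus a calibrated synthetic spectrum generator that makes
every stage testable without proprietary instrument data.

The pipeline:

1. **simulate** — generate typical and atypical mid-IR milk spectra
   (1060 points, 5012→926 cm⁻¹) with composition-linked absorbance bands,
   seasonal/farm/instrument effects and plantable atypicality archetypes
   (high fat, extraneous water, elevated free fatty acids, protein/
   carbohydrate adulteration, instrument fringes, grazing transitions).
2. **preprocess** — band selection (925–1600, 1690–1900, 2700–2971 cm⁻¹),
   per-band first derivative, standard or robust per-point scaling.
3. **screen** — a normal-milk fingerprint: freezing-point percentile filter,
   16-component PCA, latent Mahalanobis distance + reconstruction-residual
   RMSE, both z-standardized and summed into a spectrum anomaly score;
   two trim-the-top-0.1% refit iterations; monthly 0.1% prevalence flagging.
4. **cluster** — robust scaling + 24-component PCA over the flagged spectra,
   full-covariance Gaussian mixtures fitted by EM (K-means init, 50
   restarts, best log-likelihood), a K = 4…20 sweep with six evaluation
   diagnostics, and config-driven cluster merging with an advisory helper
   for instrument-split clusters.
5. **classify** — grid-searched RBF support-vector classifier on the
   cluster latent space (5-fold stratified CV, weighted F1), with an
   optional GMM-density "unassignable" gate for new spectra.
6. **report** — plot-ready tables: cluster sizes, unique-farm proportions,
   ISO-week temporal profiles, composition summaries against a reference
   band, and mean spectral deviations.

## CLI

All stages chain through a wide-CSV spectra dialect (metadata columns +
one column per wavenumber) and ZIP model archives (JSON manifest + arrays):

```sh
milkscreen --seed 7 simulate --out spectra.csv --truth-out truth.csv
milkscreen fit-screen --spectra spectra.csv --model-out screen.zip
milkscreen score --spectra spectra.csv --model screen.zip --out scores.csv
milkscreen flag --scores scores.csv --out flagged.csv
milkscreen --seed 7 fit-clusters --spectra atypical.csv --k 7 \
    --model-out cluster.zip --labels-out labels.csv --diagnostics-dir diag/
milkscreen fit-classifier --spectra atypical.csv --labels labels.csv \
    --cluster-model cluster.zip --model-out clf.zip
milkscreen classify --spectra new.csv --model clf.zip --out assigned.csv
milkscreen report --spectra atypical.csv --labels labels.csv \
    --screen-model screen.zip --out-dir report/
```

`--config <file>` accepts a YAML file overriding any stage hyperparameter
(see `milkscreen.config.DEFAULTS` for the full key set);
`--seed` controls every source of randomness; `--log-level` adjusts verbosity.

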