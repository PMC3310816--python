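# msbind

Multiple-site ensemble models of transient domain–peptide binding, fitted to
SPOT peptide-array intensities.

## The problem

Peptide-binding modules such as SH3 domains recognize short proline-rich
motifs (the classic `PxxP` core) with weak, micromolar, fast-exchanging
affinity. The peptides printed on a SPOT array are longer (13–14 residues)
than the domain's footprint (~4–8 residues), so a single spot's intensity is
not the affinity of one site: the domain transiently docks at every
*S*-residue window of the peptide, and the measured signal reflects the whole
ensemble. Models that force a single fixed binding frame onto such data
misattribute energy to the wrong residues.

`msbind` is for anyone analysing peptide-array (or similar intensity-vs-
sequence) data for short linear motif receptors: it fits both physical
pictures, compares them by cross-validation, and quantifies how localized the
bound ensemble is on each peptide.

## The model

A spot's intensity (in BLU, Boehringer light units) becomes a dimensionless
pseudo-binding energy G = −ln(BLU) in RT units. Each *S*-residue window σ of
a peptide is scored by a reference-sequence expansion truncated at single
residues,

```
G_P(σ) = J0 + Σ_s J[s, a_s],          J[s, ref(s)] ≡ 0,
```

a linear function of an indicator encoding (one intercept element, then 19
indicator slots per position — the reference residue is not counted). The two
predictors are:

* **SS (single-site)**: `G = G_P(σ_r)` for one fixed representative offset r —
  the conventional picture, fitted by multiple linear regression;
* **MS (multiple-site)**: all N−S+1 windows contribute Boltzmann terms,

  ```
  G = α − ln Σ_i exp(−G_P(σ_i)),
  ```

  fitted by restarted nonlinear least squares. The offset α absorbs the
  imperfect affine calibration of intensities to energies (J0 is fixed to 0;
  the two are confounded). Nearby extra sites can only lower G — they raise
  the bound population.

Model quality is the **normalized RMSE**: RMS prediction error on a held-out
fold divided by that fold's standard deviation (< 1 beats the trivial mean
predictor), evaluated by 10-fold cross-validation with a two-pass protocol
that fixes α at the median of the fold fits. Per-peptide binding specificity
is the **maximum local population (MLP)**: the largest Boltzmann occupancy
among a peptide's windows (1 = fully localized; 1/n = n equally shared
sites).

## A worked example

`examples/01_fit_and_recover.py` simulates one domain's array — 1,000
peptides of 13–14 residues, a hidden 6-residue energy table with
J ~ N(0, 1) RT, α = 5 RT, 0.1 RT intensity noise — and refits it:

```
simulated 1000 spots; first: VCNYLSCVNVSVCR E=+0.808 RT
SSE 8.95 over 1000 records (winning restart 2)
alpha fitted 4.97 vs true 5.00 (expressed against the truth's reference profile)
Pearson r(true J, fitted J) = 0.999
```

The SSE lands at the noise floor (n·sd² = 10) and the 114 fitted J terms
correlate at r = 0.999 with the generating table. Comparing the two models on
multi-site data (`examples/02_compare_models.py`):

```
MS normalized RMSE by window size -> S=3: 0.565, S=4: 0.147, S=5: 0.451 (best S=4)
SS normalized RMSE by window size -> S=3: 0.941, S=4: 0.914, S=5: 0.894 (best S=5)
mean percent decrease (MS vs SS): +83.4% (sd 2.4 over 10 folds)
```

The MS scan bottoms out at the generating window size (S = 4) and beats the
best single-site model on every fold. `examples/03_localization_mlp.py` and
`examples/04_scan_proteins.py` show the MLP statistic (a duplicated strong
site scores ≈ 0.5 and gains ≈ ln 2 in ensemble energy) and FASTA proteome
scanning.

There is also a thin CLI mirroring the library:

```
msbind simulate --n 1000 --true-s 6 --seed 1 --out array.tsv
msbind fit array.tsv --model ms --window 6 --out model.json
msbind compare array.tsv --scan 3..8 --out comparison.json
msbind mlp model.json array.tsv --out mlp.tsv
msbind scan-fasta model.json proteins.fasta --length 14 --out scan.tsv
```

Every run writes a JSON provenance sidecar (input hashes, seed, config,
version).

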