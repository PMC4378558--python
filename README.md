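# envdeconv

Top-down spectral deconvolution for centroided mass spectra, built around a
linear scoring function for isotopomer-envelope matches with local-FDR
calibration.

Given a centroided MS/MS spectrum, the pipeline:

1. estimates the noise intensity level (most populated intensity-histogram bin);
2. enumerates candidate envelopes by anchoring averagine theoretical
   isotopomer distributions at every (signal peak, charge state) pair;
3. matches theoretical peaks to experimental peaks (zero-intensity
   placeholders for misses), scales the theoretical pattern so its top three
   peaks carry the matched experimental intensity, prunes sub-noise peaks,
   and applies missing-peak / consecutive-run filters;
4. scores each envelope match with a per-group (k = 2, 3, 4, ≥5 peak pairs)
   linear combination of five features — m/z RMSD, a thresholded and
   asymmetrically penalized intensity distance, supporting-envelope count,
   neutral-loss-envelope count, and missing-peak count — and converts raw
   scores to local FDRs via per-group lookup tables (bin width 0.02);
5. greedily selects a non-redundant envelope set in (FDR, score) order,
   merges cross-charge duplicates, and writes a ranked monoisotopic mass
   list in an msalign-style block format.

The package also ships the training side (fragment-based labeling of
envelope matches, per-group logistic-regression weight fitting, FDR-table
building), a ground-truthed spectrum/feature simulator, and an ROC/AUC
harness comparing the combined score against single features, the
dot product, and KL divergence.

## CLI

One entry point with five subcommands (`envdeconv --help`):

```bash
# synthetic ground-truthed spectrum (two-column peak list + truth TSV)
envdeconv simulate -o spec.txt --truth truth.tsv --n-ions 10 --seed 1

# deconvolute (peak list, mzML or mzXML) into an msalign-style mass list
envdeconv deconv spec.txt -o spec.msalign --max-charge 12 --max-envelopes 20

# score all candidate envelopes without selection
envdeconv score spec.txt --max-charge 12 -o scores.tsv

# fit weights + FDR table from a spectrum annotated with a proteoform sequence
envdeconv train spec.mzML --sequence PEPTIDE... \
    --weights-out weights.txt --fdr-out fdr.txt

# per-group AUC comparison of all scorers on labeled matches
envdeconv eval spec.mzML --sequence PEPTIDE... -o auc.tsv
```

Exit codes: 0 success, 1 runtime failure, 2 usage error.

## File formats

- **Peak list** (read/write): whitespace-separated `mz intensity` lines,
  `#` comments.
- **mzML / mzXML** (read): centroided spectra only; profile scans are
  skipped with a warning.
- **Mass list** (write/read): msalign-style block —
  `BEGIN IONS` / `ID=` / optional `PRECURSOR_MZ=`, `PRECURSOR_CHARGE=`,
  `PRECURSOR_MASS=` / one tab-separated row per envelope
  (`mass intensity charge score fdr`) / `END IONS`.
- **Weights** (`src/envdeconv/data/lscore_weights.txt`): one line per group,
  columns `group d_x d_y supporting neutral_loss missing` (`-` marks the
  unused missing-peak weight of group 2).
- **FDR table** (`src/envdeconv/data/lscore_fdr.txt`): one line per 0.02-wide
  score bin, columns `group bin_index n_correct n_incorrect [smoothed_fdr]`.
  The shipped table is isotonically smoothed; regenerate with
  `python scripts/make_default_tables.py`.

## Module map

| module | contents |
| --- | --- |
| `envdeconv.isotope` | averagine composition estimation, centroided isotopomer distributions, base-peak alignment |
| `envdeconv.msio` | `Spectrum`, peak-list / mzML / mzXML readers, mass-list writer |
| `envdeconv.detect` | noise estimation, peak matching, scaling, candidate filters, support/neutral-loss annotation |
| `envdeconv.scoring` | feature computation, `WeightSet`, linear score, `FdrTable`, dot product, KL divergence |
| `envdeconv.training` | fragment mass generation, match labeling, weight fitting, FDR-table building |
| `envdeconv.deconv` | end-to-end pipeline, envelope selection, report-count estimate, mass-list merging |
| `envdeconv.simulate` | seeded synthetic spectra with ground truth; labeled feature-set generator |
| `envdeconv.evaluate` | Mann–Whitney AUC and scorer comparison tables |

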