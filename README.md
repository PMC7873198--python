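# tissuedyn

Quantitative immunofluorescence tissue cytometry in Python: measure a
stained signal (e.g. the DNA-damage-responsive transcription factor p53)
cell by cell across multi-channel tissue sections, follow it along the
intestinal crypt axis and over a post-irradiation time course, and read
out the matching transcriptional response from qPCR Ct tables.

## Who this is for

Groups doing fixed-tissue fluorescence imaging who need per-cell
quantification that is robust to the usual artifacts of slide scanning —
uneven illumination, additive background, and autofluorescent
contaminants such as red blood cells — plus the downstream summaries
used to compare tissues: top-percentile intensity estimates, positional
(crypt-to-villus) profiles, positive-cell fractions under a uniform
cutoff, and a transient-vs-sustained classification of signal dynamics.
Because public image accessions for this kind of experiment are rare,
the package ships a synthetic tissue-image generator with exported
ground truth, so every stage is validated against known answers.

## The quantification model

- **Segmentation.** Nuclei are segmented on the DAPI channel (Gaussian
  smoothing → Otsu threshold → distance-transform watershed → area
  filter) and the mask is transferred to every other channel.
- **Per-cell score.** Each nucleus is scored per channel as the mean of
  its *k* = 10 brightest pixels, `topk(c) = mean(10 largest pixels of c
  in the nucleus)` — robust to nucleus-size variation and sensitive to
  punctate staining.
- **Autofluorescence exclusion.** Cells whose unstained-control score
  exceeds `median + 5·MAD` of the sample's control distribution are
  flagged and excluded from all summaries.
- **Normalization.** `score = topk(signal) / topk(control)` (or
  `/ topk(DAPI)` for tumor sections without a control channel). Any
  smooth multiplicative illumination field applied to all channels
  cancels in this ratio.
- **Tissue summary.** The mean of the top 2% of cell scores for
  crypt-bearing tissues (the crypt population is a small bright
  minority) or the top 10% for lymphoid tissues, averaged over replicate
  samples with SEM error bars.
- **Dynamics.** A time course is classified by the late-to-peak ratio
  `r = (v(t_late) − v(0)) / (v_peak − v(0))`: *transient* if `r < 0.5`
  at `t_late = 5 h` (intestine-like pulse), *sustained* otherwise
  (spleen/thymus-like plateau).
- **qPCR.** Fold changes by `2^−ΔΔCt` with ACTB as reference gene,
  technical duplicates averaged on the Ct scale.

## Worked example

```python
import tissuedyn as td

params = td.SyntheticImageParams(seed=0)          # 10 crypts x 30 cells, Poisson noise
channels, truth = td.generate_tissue_image(params)

mask = td.segment_nuclei(channels["dapi"])
cells = td.quantify_cells(mask, channels, k=10)
cells = td.flag_autofluorescent(cells)
cells = td.normalize_cells(cells, mode="control")
kept = cells[~cells["autofluor_flag"]]

summary = td.summarize_tissue(
    {"mouse1": kept["normalized_signal"].to_numpy()},
    tissue="small_intestine", timepoint=2.0, treatment="IR", p=0.02,
)
print(f"nuclei segmented:     {mask.n_nuclei}")
print(f"autofluorescent:      {int(cells['autofluor_flag'].sum())} flagged "
      f"(truth: {len(truth.autofluor_labels)})")
print(f"top-2% summary score: {summary.summary_value:.2f} "
      f"(n={summary.n_cells} cells)")
```

prints

```
nuclei segmented:     300
autofluorescent:      15 flagged (truth: 15)
top-2% summary score: 7.68 (n=285 cells)
```

All 300 generated nuclei are recovered; the 15 autofluorescent
contaminants (5% of cells, bright in every non-DAPI channel) are flagged
exactly; and the top-2% summary of the control-normalized score, 7.68,
estimates the signal-positive crypt population (positive cells carry a
5× gain over a basal ratio of ~2 here, attenuated by the 0.9-per-cell
crypt-axis decay).

There is also a CLI for running stages from the shell:

```bash
tissuedyn simulate --config params.yaml --out sim/ --seed 1
tissuedyn segment --image sim/channels.tif --out mask.tif
tissuedyn quantify --image sim/channels.tif --mask mask.tif --out cells.csv
tissuedyn run --config pipeline.yaml --out run/     # full pipeline + manifest
```

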