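# senolytica

Quantification toolkit for fluorescence-microscopy **senolytic screening**:
finding compounds that selectively kill senescent cells while sparing their
non-senescent neighbours.

Senescent cells accumulate lipofuscin, an intrinsically fluorescent pigment
concentrated in the cytoplasm, so cytoplasmic fluorescent labels are easily
masked by autofluorescence in co-culture assays. The assay this package
supports sidesteps the problem by confining the labels to the nucleus:
quiescent cells express histone-fused **H2B-GFP**, senescent cells
**H2B-RFP**, the two are co-cultured 1:1, exposed to candidate compounds,
and the per-well nuclear counts are the readout. `senolytica` covers the
full analysis path plus the orthogonal readouts around it:

| module | what it does |
|---|---|
| `iohub` | TIFF/PNG/CSV/JSON readers and writers for fields, lambda stacks, event tables |
| `synthgen` | synthetic images/tables with planted ground truth for every stage |
| `nucleiseg` | nuclear segmentation (Gaussian smooth → Otsu → area filter → optional watershed split) and per-channel counting |
| `senolysis` | fold change to vehicle, two-tailed pooled-variance Student's t-test, verdicts |
| `sabg` | HSB-threshold quantification of X-Gal (SABG) histochemical staining |
| `spectral` | per-ROI emission spectra from 32-channel lambda stacks, nuclear vs cytoplasmic autofluorescence contrast |
| `flowgate` | DAPI gating + GFP/RFP quadrant frequencies for isolated-nuclei flow cytometry |

## The decision rule

For each condition *c* and channel (GFP, RFP), with well-level replicate
counts *x₁…xₙ* and vehicle (DMSO) counts *v₁…vₘ*:

* fold change FC = x̄ / v̄;
* p-value from the unpaired two-tailed pooled-variance Student's t-test of
  *x* against *v*;
* verdict **senolytic** ⇔ FC_RFP < 1 with p_RFP < α **and** GFP unaffected
  (p_GFP ≥ α or FC_GFP ≥ 1 − δ, quiescent drop limit δ = 0.2 by default);
  **toxic** if both channels drop significantly beyond δ;
  **quiescent-selective** if only GFP does; **inert** otherwise.

## Worked example

Simulate a 3-replicate co-culture experiment (200 cells per channel, 10%
well-level CV) in which the treatment kills 60% of senescent cells and no
quiescent cells, then score it:

```bash
senolytica simulate senolysis --survival-rfp 0.4 --seed 5 --out-dir demo
senolytica score --counts demo/counts.csv --vehicle DMSO --out demo/result.csv
```

which prints

```
treated: senolytic
DMSO: vehicle
```

and writes `demo/result.csv`:

```
condition,channel,n,mean,sd,fold_change,fold_change_sd,p_value,verdict
DMSO,GFP,3,200.66666666666666,20.108041509140897,1.0,0.10020618692262906,1.0,vehicle
treated,GFP,3,202.66666666666666,25.423086620891127,1.0099667774086378,0.12669312269547073,0.9200372179338375,senolytic
DMSO,RFP,3,194.66666666666666,18.147543451754935,1.0,0.09322368211517947,1.0,vehicle
treated,RFP,3,75.0,9.539392014169456,0.38527397260273977,0.049003726100185566,0.0005387576341192575,senolytic
```

Reading: the RFP (senescent) count fell to FC ≈ 0.385 (p ≈ 5 × 10⁻⁴,
consistent with the planted 0.4 survival) while the GFP (quiescent) count
is unchanged (FC ≈ 1.01, p ≈ 0.92) — the senolytic signature.

The image route works the same way: `senolytica simulate coculture` renders
multi-channel TIFF fields, and `senolytica count` segments and counts the
nuclei per channel. `senolytica sabg`, `senolytica spectra` and
`senolytica flow` cover the staining, spectral and flow readouts.

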