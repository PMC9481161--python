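# polarquant

Quantitative analysis tools for studying front–rear polarity in rod-shaped
bacteria such as *Myxococcus xanthus*, where a small Ras-like GTPase (MglA)
marks the leading cell pole and its GTPase-activating protein module (MglB,
boosted by the co-activator RomY) dominates the lagging pole. The package
covers the four measurement problems that come up in this kind of study:

* **Polar fluorescence quantification** (`polarquant.image_quant`) — given a
  per-cell segmentation label mask and a fluorescence image, detect polar
  clusters, partition each cell's fluorescence between the two poles and the
  cytoplasm, and bin cells into localization patterns via the snapshot
  asymmetry index

  ω = (F₁ − F₂) / (F₁ + F₂),

  where F₁ ≥ F₂ are the total cluster fluorescences at the two poles:
  unipolar (ω > 0.9), bipolar asymmetric (0.2 < ω ≤ 0.9), bipolar symmetric
  (ω ≤ 0.2), diffuse (no polar cluster). A cluster is accepted when its mean
  fluorescence exceeds the mean cytoplasmic fluorescence by two cytoplasmic
  standard deviations and it spans ≥ 3 pixels (time-lapse mode additionally
  requires a mean above twice the cytoplasmic mean).

* **Motility tracking** (`polarquant.tracking`) — link cells across
  time-lapse frames, detect reversals (sign changes of the axis-projected
  displacement, gated against jitter), compute per-interval speeds, reversal
  frequencies per reporting window, the fraction of moving cells, and the
  signed dynamic asymmetry index ω_dyn = (F_leading − F_lagging)/(F_leading
  + F_lagging) with the standard frame-inclusion rules (runs of ≥ 3 frames
  without a reversal, excluding the frames adjacent to reversals). Includes
  a hand-implemented Welch two-sample t-test for unequal variances.

* **GTPase assay kinetics** (`polarquant.kinetics`) — convert
  regenerative-coupled-assay A340 traces (1 NADH oxidized per GTP
  hydrolyzed, ε₃₄₀ = 6220 M⁻¹cm⁻¹) and malachite-green phosphate endpoints
  into specific activities in GTP per enzyme molecule per hour, with
  background subtraction, replicate averaging, fold-stimulation ratios and
  hyperbolic titration-curve fits.

* **Gene co-occurrence profiling** (`polarquant.cooccurrence`) — rank genes
  by the similarity (Jaccard, optionally phi) of their genomic
  presence/absence profile to a reference gene across a genome panel, the
  screening logic that flags candidate functional partners of a polarity
  gene.

* **Synthetic data with ground truth** (`polarquant.synthetic`) — seeded
  generators for snapshot scenes, time-lapse movies, coupled-assay traces,
  malachite plates and presence/absence matrices, so every stage of the
  pipeline can be validated end-to-end against known truth.

## Worked example

```python
from polarquant import synthetic as syn, kinetics as kin, image_quant as iq

# --- GTPase rates: generate noise-free traces at known turnover, recover them
ctx = kin.AssayContext(enzyme_conc_uM=3.0)
for label, rate in [("MglA alone", 2.0), ("MglA + MglB", 12.0),
                    ("MglA + MglB + RomY", 25.0)]:
    trace = syn.gen_coupled_trace(
        syn.CoupledAssaySpec(enzyme_conc=3.0, true_turnover=rate))
    est = kin.trace_to_turnover(kin.fit_linear_rate(trace), ctx)
    print(f"{label:<20s} {est.rate:5.2f} GTP/MglA/hr")

# --- snapshot localization: 200 cells, 81% unipolar-or-asymmetric ground truth
mix = {"unipolar": 0.48, "bipolar_asymmetric": 0.33,
       "bipolar_symmetric": 0.09, "diffuse": 0.10}
labels, fluor, truth = syn.gen_snapshot_scene(
    syn.SnapshotPopulationSpec(n_cells=200, pattern_mixture=mix,
                               noise_sd=2.5, seed=1))
records, _ = iq.quantify_scene(labels, fluor)
summary = iq.summarize_population(records)
for p in iq.PATTERNS:
    print(f"{p:<20s} {summary.percent[p]:5.1f} %")
```

prints

```
MglA alone            2.00 GTP/MglA/hr
MglA + MglB          12.00 GTP/MglA/hr
MglA + MglB + RomY   25.00 GTP/MglA/hr
unipolar              48.0 %
bipolar_asymmetric    33.5 %
bipolar_symmetric      9.5 %
diffuse                9.0 %
```

The recovered specific activities equal the generator's inputs because the
conversion (slope → M NADH/s → GTP · MglA⁻¹ · h⁻¹) inverts the generator's
arithmetic exactly on noise-free data; the classified pattern percentages
recover the 48/33/9/10 ground-truth mixture to within binomial sampling
error at n = 200 (here 81.5% of cells are unipolar or bipolar asymmetric).

A `polarquant` command-line tool exposes the same pipeline
(`polarquant simulate …`, `polarquant snapshot …`, `polarquant timelapse …`,
`polarquant kinetics …`, `polarquant cooccur …`); every run writes a
provenance record beside its outputs and is bit-reproducible for a fixed
seed.

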