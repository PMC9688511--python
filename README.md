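# flimcell

Automated single-cell analysis of fluorescence lifetime imaging (FLIM)
data, built for metabolic imaging of cultured cancer cells with NAD(P)H
autofluorescence and for tracking intrinsically fluorescent drugs such as
doxorubicin (DOX).

In TCSPC FLIM every pixel carries a histogram of photon arrival times. To
read out per-cell biology from such data, `flimcell` implements the whole
chain:

* **Phantom generation** — synthetic fields of view with elliptical cells,
  dim nuclei, Poisson photon noise, a Gaussian instrument response (IRF)
  and a full ground-truth manifest, emulating a 80 MHz two-photon TCSPC
  acquisition (12.5 ns window, ~1.5×10⁵ photons/s for 60 s per field).
* **Segmentation** — ingestion of externally produced cell/nucleus masks,
  or a classical fallback (Otsu + distance-transform watershed, dark-
  interior nucleus detection), plus nucleus/cytoplasm pairing.
* **Decay fitting** — the TCSPC histograms of all pixels in an ROI are
  summed and fitted by Poisson maximum likelihood with IRF convolution:

  - monoexponential, `A·(IRF ⊛ e^(−t/τ)) + b` — for DOX;
  - biexponential, `A·(IRF ⊛ [p·e^(−t/τ₁) + (1−p)·e^(−t/τ₂)]) + b` — for
    NAD(P)H, reporting the short/long components τ₁ < τ₂, the relative
    amplitudes a₁ + a₂ = 100%, the amplitude-weighted mean lifetime
    τₘ = (a₁τ₁ + a₂τ₂)/(a₁ + a₂), and the reduced Pearson χ² (0.8–1.2
    for a well-specified fit).

  τ₁ tracks free NAD(P)H (glycolysis-associated), τ₂ its protein-bound
  state (OXPHOS-associated); a rise in a₁ with a fall in τₘ signals a
  shift toward glycolysis.
* **Statistics** — per-cell group comparison: 1st/99th-percentile outlier
  trimming, Shapiro–Wilk normality (recorded, never gating), Welch's
  unequal-variance t-test with Bonferroni adjustment for >2 groups; plus
  Pearson and Manders M1 colocalization coefficients.

Because every phantom carries its ground truth, every stage is testable by
parameter recovery rather than by eyeballing images.

## Worked example

`examples/01_simulate_and_fit.py` simulates one cell's cytoplasm at the
baseline metabolic state (τ₁ = 0.38 ns, τ₂ = 2.7 ns, a₁ = 77%) with 10⁵
detected photons and refits it:

```
simulated photons : 100300
tau1 (free)       : 0.380 ns   (truth 0.380)
tau2 (bound)      : 2.703 ns   (truth 2.700)
a1 (free fraction): 77.3 %     (truth 77.0)
tau_m             : 0.907 ns  (truth 0.914)
reduced chi2      : 0.81  (0.8-1.2 = well specified)
```

The fitted parameters recover the ground truth to well under a percent at
a realistic single-cell photon budget, and the reduced χ² falls inside the
0.8–1.2 window expected for a correctly specified model.

The other examples cover phantom segmentation (per-object Dice scores
against ground truth), colocalization, group statistics at the literature
scale of effect (a₁ 77% vs 83%, sd 3 points, n = 40 cells/group), and the
full pipeline run. The pipeline is also exposed as a CLI:

```
flimcell all examples/configs/baseline_two_group.yaml --output-dir demo_run
```

which writes phantom scenes (TIFF + JSON), masks, a per-cell CSV and a
markdown report flagging the significant a₁ difference between the two
culture conditions.

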