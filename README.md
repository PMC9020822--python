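# capscan

Quantification toolkit for fluorescence microscopy of nucleoporin remodeling
at DNA-circle-bound nuclear pore complexes (NPCs) in budding yeast.

In ageing yeast mother cells, extrachromosomal rDNA circles (ERCs) attach to
NPCs and drag them into a crowded "cap" of the nuclear envelope adjacent to
the circle cluster. Circle-bound NPCs keep their scaffold core but lose the
nuclear basket and cytoplasmic complexes. Demonstrating this from microscopy
requires a small family of per-cell statistics, all of which this package
implements as a tested, reusable pipeline:

- **Relative accumulation (RA)** of a GFP-labeled nucleoporin in the NPC cap,
  in two variants: background-corrected,
  `RA = (I_c − I_BG) / (I_R − I_BG)`, where `I_c` and `I_R` are mean envelope
  intensities over the cap arc and the rest of the envelope and `I_BG` is
  extracellular background; and simple, `RA = I_C / I_R`.
- **Profile colocalization**: the Pearson correlation `r` between the two
  channels' intensity profiles sampled along the same nuclear-envelope line
  scan, used to ask whether a target nucleoporin still sits where a reference
  (core) nucleoporin sits.
- **Tandem-fluorescent-timer ratio**: background-corrected mCherry/sfGFP
  envelope intensity ratio, reporting the mean age of the tagged protein.
- **Nuclear/cytoplasmic ratio** of an import reporter.
- **FLIP kinetics**: normalization of fluorescence-loss-in-photobleaching
  traces to the last pre-bleach frame, acquisition-bleaching correction with
  an adjacent-cell control, and decay summaries (interpolated half-time and a
  constrained exponential rate `A·e^{−kt} + c`).
- **Replicative lifespan**: Kaplan–Meier survival curves in divisions with
  Greenwood 95% confidence bands, median RLS, and two-group log-rank tests.

Because no raw imaging data accompanies the analyses this pipeline replicates,
the package ships a **synthetic microscopy generator** with exact ground
truth: elliptical envelope rings with angularly varying NPC density, a cap
arc with configurable enrichment `E`, co-labeled channel pairs with a
configurable displaced fraction `d`, PSF blur, Poisson noise, two-compartment
FLIP traces, and Gompertz lifespan cohorts. Every quantification stage is
validated by recovering known generator parameters.

## Worked example

Simulate 20 nuclei whose true cap enrichment is `E = 2.4`, then quantify
them end to end (trace envelope → sample profiles → partition cap/rest →
background-corrected RA):

```sh
capscan simulate --out-dir demo/images --n 20 --enrichment 2.4 --seed 42
capscan quantify-cap --input-dir demo/images --out-dir demo/quant
```

`demo/quant/cells.csv` holds one row per cell:

```
  cell_id    value  log2_ra
cell_0000 2.831506 1.501569
cell_0001 2.084384 1.059621
cell_0002 2.387835 1.255703
```

and `demo/quant/summary.csv` the group summary:

```
group,n,median,mean,sem,n_excluded
all,20.0,2.3616816683486155,2.411413081984761,0.08676867906262299,0
```

The recovered median RA of 2.36 matches the generative enrichment of 2.4
within the scatter induced by the random per-cell NPC density texture and
shot noise; `log2_ra` is recorded because RA distributions are conventionally
plotted on a log2 scale. Cells whose rest-of-envelope signal does not exceed
background are excluded and counted in `exclusions.csv` rather than imputed.

The same library surface is available in Python:

```python
from capscan import (NucleusSpec, cap_channel_pair, simulate_nucleus_image,
                     cap_enrichment_from_image)

image, truth = simulate_nucleus_image(
    NucleusSpec(cap_enrichment=2.4), cap_channel_pair(), seed=0)
measurement = cap_enrichment_from_image(image)
print(measurement.value, truth.true_enrichment)
```

Other subcommands: `capscan coloc` (per-cell profile Pearson r + cohort
summary), `capscan timer`, `capscan flip`, and `capscan lifespan` (KM curves,
median RLS, pairwise log-rank table). All outputs are CSV/JSON with a
provenance header (tool version, seed, config hash), and equal inputs, config
and seed produce byte-identical files.

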