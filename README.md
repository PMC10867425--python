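# civa

Tools to **predict and stratify chromosomal-instability-aiding variants
(CIVa)** — naturally occurring loss-of-function (LoF) variants in chromosome
segregation genes such as *SPAG5* (Astrin) and *SKA3* — and to quantify their
impact on kinetochore biology from live-cell fluorescence microscopy.

The package is aimed at cell biologists and variant curators who want a
desk-scale, fully testable implementation of the three steps of a CIVa
study:

1. **Predict** (`civa.variants`, `civa.isoform`) — parse protein-level HGVS
   notation (`Q1012*`, `L7Qfs*21`, `M1?`), classify LoF consequences, merge
   heterozygous/homozygous carrier counts across population databases
   *without* pooling overlapping cohorts, and apply the prevalence filter:
   a variant is a CIVa candidate when it truncates the protein and is
   carried by at least two individuals. Truncations near the N-terminus are
   screened for rescue by alternative translation initiation: an in-frame
   downstream AUG in a Kozak context `(gcc)gccRccAUGG` (purine at −3, G at
   +4 ⇒ *strong*) can produce a functional N-terminally truncated isoform.
2. **Mimic/measure** (`civa.quantify`, `civa.tracking`) — the kinetochore
   particle tracker: detect kinetochore spots in a centromere-marker
   channel (CENPB-dsRed) with an edge filter + threshold + morphological
   clean-up, burn the mask onto the YFP/GFP measurement channel, and report
   per-particle background-subtracted intensity ratios
   `(I_kc − bg) / (I_cyto − bg)` against a ring-shaped cytoplasm proxy.
   Particles are linked through time (mutual nearest neighbour), sister
   kinetochores paired within 0.5–2.5 µm, and each pair's inter-centromere
   distance d(t) is normalized to its unstretched state T₀
   (n(t) = d(t)/d(T₀), n(T₀) = 1): reduced maximal stretch reports reduced
   microtubule-mediated pulling.
3. **Stratify** (`civa.timing`) — mitotic timing from NEBD (nuclear
   envelope breakdown) to anaphase onset on a 6-min frame grid: the
   cumulative-frequency statistic **t50** (time by which 50% of cells
   complete the transition, censored cells kept in the denominator),
   per-replicate event fractions (completion, congression, lagging
   chromosomes), and the standard tests (Mann-Whitney U, χ², paired t,
   Dunnett).

`civa.simulate` provides seeded generators with full ground truth —
two-channel 4D stacks of Gaussian sister-spot pairs with sinusoidal
breathing and a Poisson+read-noise camera model, variant cohorts with an
inbreeding coefficient F (genotype frequencies `AA: (1−q)² + q(1−q)F`,
`Aa: 2q(1−q)(1−F)`, `aa: q² + q(1−q)F`), and frame-quantized timing data —
so every stage is validated against generator truth.

## Worked example

```python
from civa.quantify import quantify_stack
from civa.simulate import ImageSimConfig, sim_image_stack

cfg = ImageSimConfig(seed=7, snr=10.0, poisson=True, n_frames=3)
stack, truth = sim_image_stack(cfg)          # 24 kinetochores, true ratio 2.0
df = quantify_stack(stack)
print(df.groupby("frame").size().tolist())   # [24, 24, 24]
print(round(df.ratio.mean(), 3))             # 1.970
```

All 24 spots are recovered in every frame and the mean
kinetochore/cytoplasm ratio (1.970) matches the generator truth of 2.0
within 1.5%. The other capabilities each have a short narrative script
under `examples/` — e.g. `python examples/variant_screen.py` prints the
merged multi-database screen in which `SKA3 Q70Kfs*7` (1906 het + 2 hom
carriers) and `SPAG5 L7Qfs*21`/`Q1012*` pass the prevalence filter, and
`python examples/kozak_scan.py` recovers the two planted strong start
sites at nt 454 (codon 152) and nt 823 (codon 275) of a synthetic
Astrin-like CDS.

A thin `civa` command exposes the same stages from a shell
(`civa screen`, `civa isoform`, `civa quantify`, `civa track`,
`civa timing`, `civa simulate`, `civa report`).

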