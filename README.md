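# clemquant

Quantification of genetically encoded particle tags in correlative
light-electron microscopy (CLEM). A ferritin-core tag ("FerriTag"-style)
appears as a ~7 nm electron-dense dot in EM sections and can be recruited
to a protein of interest by rapamycin-induced heterodimerization; this
package turns manually segmented micrographs (membrane contours + particle
centers) and two-channel live-cell stacks into the standard quantitative
readouts:

- **Region densities** — particles classified into cytoplasm, uncoated and
  coated membrane-proximal compartments (the 50-nm cytoplasmic zone),
  per-region volumes (area x 70-nm section thickness), densities in
  particles/μm³ and coat/cytoplasm fold enrichment, with one-way ANOVA +
  Tukey HSD across conditions.
- **Relative labeling intensity (RLI)** — Mayhew–Lucocq point-counting
  stereology: an 8 x 6 grid (24 interior points per image) gives expected
  compartment frequencies, scaled to the observed particle total
  (N<sub>e</sub>); RLI = N<sub>o</sub>/N<sub>e</sub>, tested with Pearson's
  χ² with Yates' continuity correction on the 2 x 2
  {observed, expected} x {cytoplasm, coated} table (df = 1).
- **Labeling resolution** — perpendicular tag-to-membrane distances,
  plus a Monte-Carlo model of detection in EM sections (tag length states
  7–18 nm, ≤ 22 nm fully extended; membrane-excluded orientations; 70-nm
  sections) summarized by the kernel-density FWHM; per-particle
  signal-to-noise ratio |mean(disc) − mean(annulus)| / SD(annulus).
- **Nanoscale pit mapping** — normalized arc positions within marked
  coated pits, pit vs distal proximity statistics (Welch's t-test), and
  the mirror-symmetric projection onto an idealized 100-nm-diameter pit.
- **Tagging kinetics** — per-spot background-subtracted channel ratios on
  binarized stacks, median-zeroed traces averaged over cells, and the
  randomized-channel control.
- **Synthetic scenes** — annotated micrographs and step-response stacks
  with known ground truth (Poisson particle placement at configurable
  per-region densities, membrane-anchored tags displaced by a
  tag-geometry draw), so every stage is testable without any image data.

It is aimed at cell biologists and image analysts quantifying immuno-EM
style labeling; inputs are coordinate annotations (a model2point-like
text dialect) with a flat key=value metadata file, not raw pixels.

## Worked example

Simulate twenty annotated micrographs at the measured density regime
(cytoplasm 72.5, coated membrane 1308.6 particles/μm³) and recover the
densities:

```sh
$ clemquant simulate --out sim --seed 11 --n-images 20
wrote 20 scene(s) to sim
$ clemquant density --points sim/scene.points --meta sim/scene.meta --out dens
synthetic: coat 1181.8 vs cyto 70.5 /um^3 (fold enrichment 16.8)
```

The recovered densities scatter around the configured 1308.6 and 72.5
(Poisson counting noise at twenty images); the fold enrichment is the
coated/cytoplasm density ratio (configured: 18-fold).

Run the Yates-corrected RLI test on a hand-written tally (observed and
expected cytoplasm/coated counts for one experiment):

```sh
$ printf 'experiment,obs_cytoplasm,obs_coated,exp_cytoplasm,exp_coated\n\
Rapamycin1,69,89,123.3,34.0\n' > tally.csv
$ clemquant stereology --tally tally.csv --out ster
experiment      chi2  df      p_value  rli_cytoplasm  rli_coated
Rapamycin1 38.479172   1 5.534116e-10       0.559611    2.617647
```

A coated-region RLI of 2.6 means 2.6x more particles at coated membrane
than expected from its areal fraction; χ² = 38.5 (df = 1) rejects random
placement at p ≈ 5.5 x 10⁻¹⁰.

Map membrane-anchored tags around a coated pit, with an extended tag
conformation at the pit (16.5–19.5 nm) and a kinked one distally
(6.5–9.5 nm):

```sh
$ cat pitscene.cfg
n_pits = 1
cytoplasm_density = 0
membrane_density = 0
coat_density = 0
anchored_rate_pit_per_nm = 0.02
anchored_rate_distal_per_nm = 0.005
tag_length_min_nm = 16.5
tag_length_max_nm = 19.5
tag_orientation = perpendicular
distal_tag_length_min_nm = 6.5
distal_tag_length_max_nm = 9.5
distal_tag_orientation = perpendicular
$ clemquant simulate --config pitscene.cfg --out psim --seed 4 --n-images 12
$ clemquant pitmap --points psim/scene.points --meta psim/scene.meta --out pm
pit 18.0±0.8 nm (n=33) vs distal 8.1±0.9 nm (n=119); Welch p=9.4e-51
```

recovering the configured ~10 nm pit-minus-distal proximity difference.
`pm/idealized_coordinates.csv` holds the mirror-symmetric idealized-pit
projection (two points per particle).

Simulate the labeling-resolution distribution under the default
tag-geometry model:

```sh
$ clemquant resolution --simulate --n-draws 100000 --out res --seed 1
simulated: n=100000 median=11.33 nm FWHM=9.89 nm max=17.99 nm
```

The FWHM of ~10 nm is the labeling resolution: a detected particle sits
about 10 ± 5 nm from the tagged protein, and never beyond the 22-nm fully
extended geometry.

See `docs/methods.md` for the models, parameter defaults, and numerical
choices behind each stage.

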