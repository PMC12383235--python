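# prefibril

Quantitative analysis of amyloid-β (Aβ42) **prefibrillar assemblies** — the
small oligomers, curvilinear protofibrils ("extended oligomers") and annular
pore-forming rings that dominate the lag phase of amyloid fibril formation
and are the species most strongly linked to cytotoxicity in Alzheimer's
disease.

The package is written for structural biologists and biophysicists who
quantify these assemblies from atomic force microscopy (AFM) height maps,
cryo-EM/cryo-ET density images and volumes, thioflavin T (ThT) aggregation
kinetics, and single-channel patch-clamp recordings. It provides:

* **morphometry** — filament tracing (skeleton → longest geodesic path),
  arc lengths, cross-sectional diameters at the *15%-above-baseline*
  convention, AFM heights above a fitted support plane, annular ring
  inner/outer diameters and channel lengths, and length-distribution
  statistics (median, Freedman–Diaconis modal length);
* **kinetics** — ThT curve normalization and lag-end timing (first 10%
  crossing), per-frame tracking of bidirectionally elongating oligomers in
  AFM time series, per-end growth rates by ordinary least squares, and
  Fluo-4 influx normalization (F/F₀ − 1);
* **ephys** — conductance series g = I/V on step-voltage protocols,
  open/closed idealization by half-amplitude threshold, windowed modal
  conductance (2500 ms windows), and the Hille access-resistance pore model;
* **stoichiometry** — map volume → mass → monomer count (825 Da/nm³),
  filament length → monomer count (0.48 nm cross-β strand rise per monomer);
* **synthetic_data** — generators for every input modality with exact
  ground truth, so every stage is testable end to end with no external data.

## The core model: pore conductance ↔ pore diameter

A non-selective cylindrical pore of diameter *d* and length *l* in a
solution of resistivity ρ has total resistance equal to the cylinder
resistance plus one access (convergence) resistance ρ/(2d) at each mouth:

```
1/g = 4ρl/(πd²) + ρ/d
```

Solving the quadratic for the positive root,

```
d = [ ρg + √((ρg)² + 16 ρ g l / π) ] / 2,        d → ρg as l → 0
```

with ρg expressed in length units (80 Ω·cm × 1 pS = 10⁻⁵ nm). With the
channel length *l* = 5.4 nm measured from the annular-assembly
reconstruction and ρ = 80 Ω·cm, the typical single-channel conductance of
320 pS corresponds to a pore diameter of **1.46 nm**, and the typical
conductance range 135–540 pS to diameters of ≈1.0–2.0 nm — matching the
internal channel diameter seen in the 3D reconstructions (1.0–2.4 nm
across methods).

## Worked example

Convert geometry and rates to stoichiometry, apply the pore model, and
run the full simulate → track → fit loop:

```sh
$ prefibril stoich --length-nm 48 --rate-nm-min 8.0
{
 "length": {"input_value": 48.0, "mass_kda_2sf": 450.0, "monomer_count": 100, ...},
 "monomers_per_min": 16.666666666666668
}
```

A 48 nm curvilinear protofibril contains 100 Aβ monomers (≈450 kDa) at one
0.48 nm β-strand per monomer, and an end growing at 8 nm/min adds ≈16.7
monomers per minute.

```sh
$ prefibril ephys --hille --g-ps 320 --l-nm 5.4 --rho 80
{"d_nm": 1.4608579619156306, "g_ps": 320.0, ...}
```

```sh
$ prefibril simulate-afm --rate-a 8 --rate-b 8 --seed 1 --out series.tiff
$ prefibril growth series.tiff --out growth.json --plot fit.png
$ python -c "import json; print(json.load(open('growth.json'))['rates'])"
{'rate_a': 8.037, 'rate_b': 7.63, 'r_squared_a': 0.999, 'r_squared_b': 0.999,
 'monomers_per_min_a': 16.745, 'monomers_per_min_b': 15.895}
```

The simulated oligomer (true rates 8.0/8.0 nm/min, 8-min frames, 12 nm
pixels, 20 nm tip) is re-traced frame by frame; the fitted per-end rates
recover the ground truth to within a few percent with r² ≈ 1, mirroring
the linearity of real-time AFM elongation measurements.

Every output JSON embeds the resolved configuration, its hash, and the
package version; the same configuration and seed reproduce byte-identical
CSV/JSON artifacts.

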