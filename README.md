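# beamlab

Monte Carlo modelling and dosimetry toolkit for thermal-neutron-filtered
accelerator BNCT (boron neutron capture therapy) beams.

The package implements the full evaluation chain for a LiF thermal-neutron
filtration system at desk scale:

* **source** — parametric stand-in for the (proprietary) accelerator exit
  spectrum: Maxwellian thermal + 1/E epithermal + soft evaporation fast tail,
  emitted from a planar disc with a cos^m angular law.
* **nuclear** — nuclide/material registry with 1/v capture cross sections
  anchored at 2200 m/s, free-atom scattering, KERMA constants, and photon
  attenuation data (versioned YAML constants file with provenance comments).
* **geometry** — prioritized box/cylinder/annulus scenes for the collimator +
  filter designs A (full disc), B (central square), C (disc + square), plus a
  voxel-lattice override for patient phantoms.
* **transport** — analog (or implicit-capture) neutron/photon Monte Carlo
  with track-length fluence tallies, 1/v-folded fluence tallies, per-channel
  capture maps, hydrogen-recoil energy deposition, and batch-statistics
  errors (numba-accelerated kernels).
* **dose** — four-component KERMA dosimetry (boron / nitrogen / hydrogen /
  gamma) and RBE/CBE biological weighting for tumor, normal-tissue and skin
  roles.
* **metrics** — advantage depth, maximum treatment time, skin dose at
  delivery, off-axis flatness, proton-current scaling.
* **activation** — gold-wire reaction-rate recovery from counting data under
  a pulsed-charge schedule, cadmium-difference thermal flux.
* **dvh / patient** — HU-to-material conversion, synthetic head phantom with
  four mock tumors, end-to-end irradiation normalized to a 12.5 Gy brain
  maximum, cumulative DVH curves, D_p percentiles, homogeneity index.

## CLI

```bash
beamlab makesource --out spectrum.txt
beamlab pipeline --config run.yaml --seed 1 --out results/
beamlab simulate --config run.yaml --seed 1 --out results/   # + HDF5 tallies
beamlab metrics --tumor tumor.csv --nt nt.csv --report metrics.csv
beamlab activation --meas meas.csv --schedule charge.csv
beamlab rescale --mtt 75.6 --current 2.0
beamlab dvh --design C --histories 200000 --out dvh.csv
```

A run configuration is a YAML file with `source:`, `geometry:`,
`transport:`, `weights:` and `outputs:` blocks; every artifact is
regenerable from the config plus the seed (a manifest with the config hash
is written next to the outputs).  `geometry.disc_thickness` may be a list to
run a filter-thickness sweep (e.g. `[2.5, 5, 7.5, ..., 20]`).

Example:

```yaml
source:     {disc_radius: 7.0}
geometry:   {design: A, disc_thickness: 5.0, phantom_material: brain}
transport:  {n_particles: 200000, bin_cm: 0.4}
```

## Notes

* The true accelerator spectrum is not public; all beam-dependent numbers
  (advantage depth, treatment times, skin doses) are therefore produced for
  the synthetic stand-in beam and validated as trends/orderings, not as the
  published absolute values.
* Dose rates are reported in Gy/h at a configurable reference source
  strength (particles/s/mA); treatment-time metrics scale inversely with the
  proton current.
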