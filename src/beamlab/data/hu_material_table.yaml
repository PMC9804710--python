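# Hounsfield-unit -> (material bin, mass density) conversion.
#
# Piecewise-linear density curve in the style of the stoichiometric CT
# calibrations used for Monte Carlo treatment planning: air plateau below
# -1000 HU, water-like linear ramp through (0 HU, 1.0 g/cm3), and a shallower
# bone ramp above +100 HU.  Material bins are coarse transport classes.
hu_window: [-1024, 3000]

density_curve:   # (HU, g/cm3) nodes, linear in between, clamped outside
  - [-1024, 0.00121]
  - [-1000, 0.00121]
  - [0,     1.000]
  - [100,   1.076]
  - [3000,  2.757]

material_bins:   # upper HU bound (exclusive) -> material label
  - [-950, air]
  - [-200, lung]
  - [-20,  adipose]
  - [120,  soft_tissue]
  - [3001, bone]
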