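# Point nuclear constants used by beamlab.
#
# Thermal (2200 m/s, E0 = 0.0253 eV) capture cross sections and free-atom
# elastic scattering cross sections, from standard evaluated-data compilations
# (Mughabghab thermal constants / ENDF thermal points, rounded).  Capture is
# extrapolated off the anchor point with the 1/v law; scattering is treated as
# energy independent below the fast band.
#
# sigma0_capture : barns at 0.0253 eV
# sigma_scatter  : barns, free atom
# atomic_mass    : amu
# Z              : proton number (used for photon electron-density scaling)
# capture_channel: reaction bookkeeping label
# q_local_mev    : energy (MeV) deposited locally per capture under the KERMA
#                  approximation (charged products only; for B-10 the weighted
#                  2.31/2.79 MeV branch average with the 478 keV photon folded
#                  into the constant; for H-1 the 2.22 MeV capture photon is
#                  transported, not deposited locally, hence 0).

energy_anchor_ev: 0.0253

nuclides:
  H1:   {atomic_mass: 1.0078,  Z: 1,  sigma0_capture: 0.3326, sigma_scatter: 20.49, has_1v_capture: true,  capture_channel: "H1(n,g)",    q_local_mev: 0.0}
  Li6:  {atomic_mass: 6.0151,  Z: 3,  sigma0_capture: 940.0,  sigma_scatter: 0.75,  has_1v_capture: true,  capture_channel: "Li6(n,a)t",  q_local_mev: 4.78}
  Li7:  {atomic_mass: 7.0160,  Z: 3,  sigma0_capture: 0.0454, sigma_scatter: 1.07,  has_1v_capture: true,  capture_channel: "Li7(n,g)",   q_local_mev: 0.0}
  B10:  {atomic_mass: 10.0129, Z: 5,  sigma0_capture: 3837.0, sigma_scatter: 2.23,  has_1v_capture: true,  capture_channel: "B10(n,a)",   q_local_mev: 2.34}
  B11:  {atomic_mass: 11.0093, Z: 5,  sigma0_capture: 0.0055, sigma_scatter: 4.07,  has_1v_capture: true,  capture_channel: "B11(n,g)",   q_local_mev: 0.0}
  C12:  {atomic_mass: 12.0110, Z: 6,  sigma0_capture: 0.0035, sigma_scatter: 4.74,  has_1v_capture: true,  capture_channel: "C12(n,g)",   q_local_mev: 0.0}
  N14:  {atomic_mass: 14.0067, Z: 7,  sigma0_capture: 1.83,   sigma_scatter: 10.05, has_1v_capture: true,  capture_channel: "N14(n,p)",   q_local_mev: 0.626}
  O16:  {atomic_mass: 15.9994, Z: 8,  sigma0_capture: 0.00019, sigma_scatter: 3.75, has_1v_capture: true,  capture_channel: "O16(n,g)",   q_local_mev: 0.0}
  F19:  {atomic_mass: 18.9984, Z: 9,  sigma0_capture: 0.0096, sigma_scatter: 3.64,  has_1v_capture: true,  capture_channel: "F19(n,g)",   q_local_mev: 0.0}
  P31:  {atomic_mass: 30.9738, Z: 15, sigma0_capture: 0.172,  sigma_scatter: 3.31,  has_1v_capture: true,  capture_channel: "P31(n,g)",   q_local_mev: 0.0}
  Ca:   {atomic_mass: 40.078,  Z: 20, sigma0_capture: 0.43,   sigma_scatter: 2.78,  has_1v_capture: true,  capture_channel: "Ca(n,g)",    q_local_mev: 0.0}
  Au197: {atomic_mass: 196.9666, Z: 79, sigma0_capture: 98.65, sigma_scatter: 7.8,  has_1v_capture: true,  capture_channel: "Au197(n,g)", q_local_mev: 0.0}

# Elemental mass fractions.  Tissue compositions follow the ICRP/ICRU
# reference tables (minor trace elements folded into oxygen); densities in
# g/cm3.  Lithium entries are per-element here; the Li-6/Li-7 split is set at
# build time from the enrichment (natural Li = 7.59 atom% Li-6).
materials:
  water:
    density: 1.0
    formula: {H: 2, O: 1}
  pmma:
    density: 1.19
    formula: {C: 5, H: 8, O: 2}
  air:
    density: 0.0012
    mass_fractions: {N: 0.755, O: 0.245}
  brain:       # ICRP adult brain
    density: 1.04
    mass_fractions: {H: 0.107, C: 0.145, N: 0.022, O: 0.726}
  soft_tissue: # ICRU four-component soft tissue
    density: 1.0
    mass_fractions: {H: 0.101, C: 0.111, N: 0.026, O: 0.762}
  skin:        # ICRP skin
    density: 1.09
    mass_fractions: {H: 0.100, C: 0.204, N: 0.042, O: 0.654}
  adipose:
    density: 0.95
    mass_fractions: {H: 0.114, C: 0.598, N: 0.007, O: 0.281}
  lung:
    density: 0.26
    mass_fractions: {H: 0.103, C: 0.105, N: 0.031, O: 0.761}
  bone:        # cortical bone, trace folded into O
    density: 1.92
    mass_fractions: {H: 0.034, C: 0.155, N: 0.042, O: 0.435, P: 0.103, Ca: 0.231}
  polyethylene:
    density: 0.94
    formula: {C: 1, H: 2}

# Photon attenuation for water (NIST-style mass coefficients, cm2/g).
# Other materials are scaled by their electron density relative to water;
# adequate in the Compton-dominated band the capture gammas occupy.
photon_water:
  energy_mev:  [0.01, 0.05, 0.1, 0.5, 1.0, 2.0, 3.0, 5.0, 10.0]
  mu_rho:      [5.329, 0.2269, 0.1707, 0.0969, 0.0707, 0.0494, 0.0397, 0.0303, 0.0222]
  mu_en_rho:   [4.944, 0.04188, 0.02546, 0.0330, 0.0310, 0.0260, 0.0227, 0.0190, 0.0157]
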