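# Membrane and geometry parameter table "mrg_5p7um_v1"
#
# MRG-style myelinated motor axon, 5.7 um fiber diameter, 0.5 mm internodal
# distance, reduced to four compartments per section: node of Ranvier, two
# flanking paranodes (MYSA+FLUT merged), and one lumped internode.  Node
# kinetics: fast Na+, persistent Na+, slow K+, leak at 36 C.  Myelinated
# compartments are passive, with capacitance and conductance reduced by the
# myelin lamellae acting in series with the axolemma.
#
# Units: lengths um, diameters um, capacitances uF/cm^2, conductances S/cm^2,
# potentials mV, resistivity Ohm*cm.
name: mrg_5p7um_v1
fiber_diameter_um: 5.7
internodal_distance_um: 500.0

geometry:
  node_length_um: 1.0
  node_diameter_um: 1.9
  paranode_length_um: 38.0     # MYSA (3 um) + FLUT (35 um), merged
  paranode_diameter_um: 3.4
  internode_diameter_um: 3.4   # internode length = 500 - 1 - 2*38 = 423 um
  n_myelin_lamellae: 80

electrical:
  axial_resistivity_ohm_cm: 70.0
  node:
    cm_uF_per_cm2: 2.0
    g_naf_S_per_cm2: 3.0
    g_nap_S_per_cm2: 0.01
    g_ks_S_per_cm2: 0.08
    g_leak_S_per_cm2: 0.007
    e_na_mV: 50.0
    e_k_mV: -90.0
    e_leak_mV: -90.0
  myelinated:
    # axolemma (2 uF/cm^2, 1e-4 S/cm^2) in series with 80 lamellae
    # (2 membranes each at 0.1 uF/cm^2 and 1e-3 S/cm^2 per lamella membrane)
    cm_uF_per_cm2: 6.25e-4
    g_pas_S_per_cm2: 5.9e-6
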