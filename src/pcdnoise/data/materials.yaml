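# Converter and phantom material constants.
#
# K-shell parameters: edge energies and mean K x-ray emission energies are
# intensity-weighted Kalpha/Kbeta mixtures from standard emission-line
# tables; fluorescence yields from standard compilations.  The K-shell
# participation fraction (fraction of photoelectric interactions that
# involve the K shell above the edge) is derived at load time from the
# photoelectric jump of the embedded attenuation tables.
cdte:
  description: Stoichiometric CdTe converter at CZT bulk density
  density_g_cm3: 6.2
  w_pair_kev: 0.005        # electron-hole pair creation energy (5 eV)
  fano: 1.0                # Poisson conversion gain assumed for noise analysis
  fano_intrinsic: 0.1      # physical Fano factor of CdTe/CZT
  elements:
    - symbol: cd
      mass_fraction: 0.46836
      k_edge_kev: 26.711
      fluorescence_yield: 0.843
      mean_k_xray_kev: 23.62
    - symbol: te
      mass_fraction: 0.53164
      k_edge_kev: 31.814
      fluorescence_yield: 0.875
      mean_k_xray_kev: 28.02
bone_cortical:
  description: ICRU-44 cortical bone (phantom material for spectral imaging)
  density_g_cm3: 1.92
aluminum:
  description: Filtration material
  density_g_cm3: 2.699
tungsten:
  description: X-ray tube anode
  density_g_cm3: 19.3
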