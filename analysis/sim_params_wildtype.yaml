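# Wild-type-like SK1 dissection experiment for `tetrakit simulate`.
# Marker spacing follows the mapped wild-type distances on chromosomes
# III, VII and VIII; chromosome lengths and centromere placements are
# order-of-magnitude choices (only the marker spacing is calibrated).
n_tetrads: 500
seed: 0
interference_m: 3            # counting-model order; every 4th precursor matures
noninterfering_fraction: 0.2 # share of crossovers through the Poisson pathway
conversion_prob: 0.01        # per marker per meiosis (3:1 / 1:3 events)
ndj_prob_e0: 0.5             # MI nondisjunction odds for an achiasmate bivalent
chromosomes:
  III:
    length_m: 1.15
    centromere_m: 0.499
    disome_viable: true      # III disomes survive as MATa/MATalpha non-maters
    centromere_marker: CEN3
    mating_type_marker: MAT
    markers:
      HIS4: 0.300
      LEU2: 0.438
      CEN3: 0.499
      MAT: 0.648
  VII:
    length_m: 4.0
    centromere_m: 1.10
    markers:
      TRP5: 1.000
      CYH2: 1.360
      MET13: 1.453
      LYS5: 1.664
  VIII:
    length_m: 2.0
    centromere_m: 0.750
    centromere_marker: CEN8
    markers:
      CEN8: 0.750
      THR1: 0.965
      CUP1: 1.212
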