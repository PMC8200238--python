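# c13referee synthetic shift model, increment tables, version 1
#
# Additive 13C chemical-shift increments used by the fixture generator.
# The model is intentionally a function of the <=3-bond environment so that
# carbons sharing a sphere-3 spherical-environment code receive identical
# base values; anchors: terminal alkane CH3 ~14 ppm, chain positions 22/32,
# interior CH2 ~29 ppm, benzene 128.5 ppm, bromine ipso -6 ppm, nitrile
# ipso -16 ppm.  Para increments are harmonized within groups sharing the
# same substituent first atom, because a 4-sphere environment code cannot
# see further than the first substituent atom from the para position.
version: 1
noise_sigma: 0.5   # ppm, Gaussian noise per equivalence class

sp3:
  base: -2.3
  carbon: [9.1, 9.4, -2.5]      # alpha/beta/gamma increments per carbon
  hetero:                        # alpha/beta/gamma increments per element
    O: [47.0, 9.5, -5.5]
    N: [27.0, 10.5, -4.8]
    S: [20.0, 7.0, -3.0]
    F: [68.0, 9.0, -4.0]
    Cl: [31.0, 10.0, -4.6]
    Br: [19.0, 10.5, -3.5]
    I: [-7.0, 11.0, -1.5]

aromatic:
  base: 128.5
  # substituent key: [ipso, ortho, meta, para]
  substituents:
    CH3:   [9.3, 0.7, -0.1, -2.9]
    alkyl: [15.7, -0.6, -0.1, -2.8]
    OH:    [26.9, -12.7, 1.4, -7.3]
    OMe:   [31.4, -14.4, 1.0, -7.7]
    OR:    [29.2, -13.6, 1.1, -8.1]
    NH2:   [18.0, -13.3, 0.9, -9.8]
    NR:    [21.5, -15.0, 0.8, -11.0]
    F:     [34.8, -12.9, 1.4, -4.5]
    Cl:    [6.2, 0.4, 1.3, -1.9]
    Br:    [-6.0, 3.4, 1.7, -1.6]    # ipso per the ~6 ppm upfield bromo effect
    I:     [-34.1, 8.9, 1.6, -1.1]
    CN:    [-16.0, 3.6, 0.6, -2.8]    # ipso per the ~16 ppm upfield nitrile effect
    CHO:   [8.6, 1.3, 0.6, -2.8]
    acyl:  [9.1, 0.1, 0.0, -2.8]
    COOR:  [2.1, 1.1, 0.0, -2.8]
    aryl:  [13.1, -1.1, 0.4, -1.1]
    vinyl: [9.5, -2.0, 0.2, -2.8]
    generic: [8.0, 0.5, 0.0, 0.0]

sp2:
  base: 123.0
  # increments for substituents on the carbon itself (alpha) and on its
  # double-bond partner (beta)
  alpha: {C: 11.0, O: 18.0, N: 14.0, S: 9.0, F: 24.0, Cl: 3.0, Br: -1.0, I: -38.0}
  beta:  {C: -8.0, O: -27.0, N: -24.0, S: -12.0, F: -34.0, Cl: -6.0, Br: -1.0, I: 7.0}
  aromatic_alpha: 10.0   # aryl substituent on the sp2 carbon
  aromatic_beta: -6.0

carbonyl:
  ketone: 205.0
  aldehyde: 192.0
  acid: 172.0
  ester: 166.0
  amide: 170.0
  conjugation: -7.0      # per aryl/vinyl neighbor

other:
  nitrile: 118.0
  alkyne: 80.0
  alkyne_terminal: 70.0
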