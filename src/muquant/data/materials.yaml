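# Material registry: elemental mass fractions and densities used by the
# digital phantoms.  Tissue entries are ICRU-44-style compositions; the
# plastic-water entry is a generic water-equivalent surrogate.
materials:
  lung_inhale:
    density: 0.204
    composition:
      H: 0.103
      C: 0.105
      N: 0.031
      O: 0.749
      Na: 0.002
      P: 0.002
      S: 0.003
      Cl: 0.003
      K: 0.002
  lung_exhale:
    density: 0.496
    composition:
      H: 0.103
      C: 0.105
      N: 0.031
      O: 0.749
      Na: 0.002
      P: 0.002
      S: 0.003
      Cl: 0.003
      K: 0.002
  adipose:
    density: 0.96
    composition:
      H: 0.114
      C: 0.598
      N: 0.007
      O: 0.278
      Na: 0.001
      S: 0.001
      Cl: 0.001
  breast:
    density: 0.991
    composition:
      H: 0.106
      C: 0.332
      N: 0.03
      O: 0.527
      Na: 0.001
      P: 0.001
      S: 0.002
      Cl: 0.001
  muscle:
    density: 1.062
    composition:
      H: 0.102
      C: 0.143
      N: 0.034
      O: 0.71
      Na: 0.001
      P: 0.002
      S: 0.003
      Cl: 0.001
      K: 0.004
  liver:
    density: 1.07
    composition:
      H: 0.102
      C: 0.139
      N: 0.03
      O: 0.716
      Na: 0.002
      P: 0.003
      S: 0.003
      Cl: 0.002
      K: 0.003
  bone_200:
    density: 1.16
    composition:
      Ca: 0.06878293
      H: 0.09295291
      O: 0.80636919
      P: 0.03189497
  bone_800:
    density: 1.52
    composition:
      Ca: 0.20996821
      H: 0.05406105
      O: 0.63860764
      P: 0.0973631
  bone_1250:
    density: 1.82
    composition:
      Ca: 0.273997
      H: 0.036424
      O: 0.562525
      P: 0.127054
  plastic_water:
    density: 1.035
    composition:
      H: 0.0809
      C: 0.6722
      N: 0.024
      O: 0.1984
      Cl: 0.0013
      Ca: 0.0232
  water:
    density: 0.998
    composition:
      H: 0.1119
      O: 0.8881
  air:
    density: 0.001205
    composition:
      C: 0.0003
      N: 0.7551
      O: 0.2318
      Ar: 0.0128
  soft_tissue:
    density: 1.03
    composition:
      H: 0.105
      C: 0.256
      N: 0.027
      O: 0.602
      Na: 0.001
      P: 0.002
      S: 0.003
      Cl: 0.002
      K: 0.002
  cortical_bone:
    density: 1.92
    composition:
      H: 0.034
      C: 0.155
      N: 0.042
      O: 0.435
      Na: 0.001
      Mg: 0.002
      P: 0.103
      S: 0.003
      Ca: 0.225
  hydroxyapatite:
    density: 3.16
    composition:
      Ca: 0.398939
      H: 0.002007
      O: 0.414064
      P: 0.18499
  polystyrene_foam:
    density: 0.023
    composition:
      H: 0.0774
      C: 0.9226
  ptfe:
    density: 2.18
    composition:
      C: 0.2402
      F: 0.7598
  polyamide:
    density: 1.02
    composition:
      H: 0.09799
      C: 0.63686
      N: 0.12378
      O: 0.14137
  polypropylene:
    density: 0.91
    composition:
      H: 0.1437
      C: 0.8563
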