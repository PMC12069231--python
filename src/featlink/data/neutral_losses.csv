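name,formula,mass
H2O,H2O,18.010565
NH3,NH3,17.026549
CO,CO,27.994915
CO2,CO2,43.989829
HCOOH,CH2O2,46.005480
CH2O,CH2O,30.010565
C2H4O2,C2H4O2,60.021129
anhydrohexose,C6H10O5,162.052824
anhydropentose,C5H8O4,132.042259
anhydrodeoxyhexose,C6H10O4,146.057909
SO3,SO3,79.956815
H3PO4,H3PO4,97.976896
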