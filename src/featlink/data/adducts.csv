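name,ion_mode,multiplicity,charge,mass_shift
[M+H]+,positive,1,1,1.007276
[M+Na]+,positive,1,1,22.989218
[M+K]+,positive,1,1,38.963158
[M+NH4]+,positive,1,1,18.033823
[2M+H]+,positive,2,1,1.007276
[2M+Na]+,positive,2,1,22.989218
[M+2H]2+,positive,1,2,2.014552
[M+H-H2O]+,positive,1,1,-17.003289
[M+2Na-H]+,positive,1,1,44.971160
[M-H]-,negative,1,-1,-1.007276
[M+Cl]-,negative,1,-1,34.969402
[M+HCOO]-,negative,1,-1,44.998201
[M+CH3COO]-,negative,1,-1,59.013851
[2M-H]-,negative,2,-1,-1.007276
[M-2H]2-,negative,1,-2,-2.014552
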