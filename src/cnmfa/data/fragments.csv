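# TBDMS-derivatized proteinogenic amino acid fragment ions detected by GC-MS.
# [M-57] = derivatized molecule - C4H9 (retains all amino-acid carbons);
# [M-85] = derivatized molecule - C4H9 - CO (loses the C1 carboxyl carbon).
# Exclusion flags carry the default measurement-quality policy:
# Tyr/Lys low signal-to-noise, Pro co-elution with another compound.
amino_acid,kind,m0_mz,backbone_carbons,formula,excluded,exclude_reason
Ala,M-57,260,3,C11H26NO2Si2,False,
Ala,M-85,232,2,C10H26NOSi2,False,
Gly,M-57,246,2,C10H24NO2Si2,False,
Gly,M-85,218,1,C9H24NOSi2,False,
Val,M-57,288,5,C13H30NO2Si2,False,
Val,M-85,260,4,C12H30NOSi2,False,
Leu,M-57,302,6,C14H32NO2Si2,False,
Leu,M-85,274,5,C13H32NOSi2,False,
Ile,M-57,302,6,C14H32NO2Si2,False,
Ile,M-85,274,5,C13H32NOSi2,False,
Pro,M-57,286,5,C13H28NO2Si2,True,co-elution
Pro,M-85,258,4,C12H28NOSi2,True,co-elution
Met,M-57,320,5,C13H30NO2SSi2,False,
Met,M-85,292,4,C12H30NOSSi2,False,
Ser,M-57,390,3,C17H40NO3Si3,False,
Ser,M-85,362,2,C16H40NO2Si3,False,
Thr,M-57,404,4,C18H42NO3Si3,False,
Thr,M-85,376,3,C17H42NO2Si3,False,
Phe,M-57,336,9,C17H30NO2Si2,False,
Phe,M-85,308,8,C16H30NOSi2,False,
Asp,M-57,418,4,C18H40NO4Si3,False,
Asp,M-85,390,3,C17H40NO3Si3,False,
Glu,M-57,432,5,C19H42NO4Si3,False,
Glu,M-85,404,4,C18H42NO3Si3,False,
Lys,M-57,431,6,C20H47N2O2Si3,True,low signal-to-noise
Lys,M-85,403,5,C19H47N2OSi3,True,low signal-to-noise
Tyr,M-57,466,9,C23H44NO3Si3,True,low signal-to-noise
Tyr,M-85,438,8,C22H44NO2Si3,True,low signal-to-noise
His,M-57,440,6,C20H42N3O2Si3,False,
His,M-85,412,5,C19H42N3OSi3,False,
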