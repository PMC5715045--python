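# Central carbon metabolism of Cupriavidus necator H16 with carbon atom
# transitions (1-based, C1 = carboxyl/aldehyde end; one lowercase letter per
# carbon).  Pathways: fructose entry to the Entner-Doudoroff route (no
# phosphofructokinase, no 6-phosphogluconate dehydrogenase), glycerol
# assimilation via glycerol-3-phosphate, non-oxidative pentose phosphate
# pathway, CBB carboxylation by RuBisCO, lower glycolysis/gluconeogenesis,
# TCA cycle with glyoxylate shunt, anaplerosis (PPC/PCK/PYC/MaeB), PHB
# synthesis, and proteinogenic amino acid formation from their precursors.
# Carbon released or fixed is mapped explicitly to the CO2 pool.
rxn_id,equation,atom_transition,class,lb,ub
upt_fru,FRUx -> FRU,abcdef > abcdef,measured,0,20
frk,FRU -> F6P,abcdef > abcdef,dependent,0,20
upt_glyc,GLYCx -> GLYC,abc > abc,measured,0,20
glpK,GLYC -> GLY3P,abc > abc,dependent,0,20
glpD,GLY3P -> DHAP,abc > abc,dependent,0,20
pgi,G6P <-> F6P,abcdef > abcdef,dependent,-20,20
zwf,G6P -> 6PG,abcdef > abcdef,dependent,0,20
edd,6PG -> KDPG,abcdef > abcdef,dependent,0,20
eda,KDPG -> PYR + G3P,abcdef > abc + def,dependent,0,20
fba,F16P <-> DHAP + G3P,abcdef > abc + def,dependent,-20,20
fbp,F16P -> F6P,abcdef > abcdef,dependent,0,20
tpi,DHAP <-> G3P,abc > cba,dependent,-20,20
gap,G3P <-> 13PG,abc > abc,dependent,-20,20
pgk,13PG <-> 3PG,abc > abc,dependent,-20,20
gpm,3PG <-> 2PG,abc > abc,dependent,-20,20
eno,2PG <-> PEP,abc > abc,dependent,-20,20
pyk,PEP -> PYR,abc > abc,free,0,5
pdh,PYR -> ACCOA + CO2,abc > bc + a,dependent,0,20
rpi,RU5P <-> R5P,abcde > abcde,dependent,-20,20
rpe,RU5P <-> X5P,abcde > abcde,dependent,-20,20
tktA,X5P + R5P <-> S7P + G3P,abcde + fghij > abfghij + cde,dependent,-20,20
tal,S7P + G3P <-> E4P + F6P,abcdefg + hij > defg + abchij,dependent,-20,20
tktB,X5P + E4P <-> F6P + G3P,abcde + fghi > abfghi + cde,dependent,-20,20
prk,RU5P -> RU15P,abcde > abcde,dependent,0,20
rbc,RU15P + CO2 -> 3PG + 3PG,abcde + f > fba + cde,free,0,5
glt,OAA + ACCOA -> CIT,abcd + ef > efbcda,dependent,0,20
acn,CIT <-> ICIT,abcdef > abcdef,dependent,-20,20
icd,ICIT -> AKG + CO2,abcdef > edcba + f,dependent,0,20
suca,AKG -> SUCOA + CO2,abcde > bcde + a,dependent,0,20
sucd,SUCOA -> SUC,abcd > abcd,dependent,0,20
sdh,SUC <-> FUM,abcd > abcd,dependent,-20,20
fum,FUM <-> MAL,abcd > abcd,dependent,-20,20
mdh,MAL <-> OAA,abcd > abcd,dependent,-20,20
icl,ICIT -> SUC + GLOX,abcdef > abde + fc,free,0,5
mls,GLOX + ACCOA -> MAL,ab + cd > abdc,dependent,0,20
ppc,PEP + CO2 -> OAA,abc + d > abcd,free,0,5
pck,OAA -> PEP + CO2,abcd > abc + d,free,0,5
pyc,PYR + CO2 -> OAA,abc + d > abcd,free,0,5
mae,MAL -> PYR + CO2,abcd > abc + d,free,0,5
phaA,ACCOA + ACCOA -> AACOA,ab + cd > abcd,free,0,2
phaBC,AACOA -> PHB,abcd > abcd,dependent,0,20
ala_syn,PYR -> ALA,abc > abc,dependent,0,20
ser_syn,3PG -> SER,abc > abc,dependent,0,20
shm,SER -> GLY + MTHF,abc > ab + c,dependent,0,20
gcv,GLY -> MTHF + CO2,ab > b + a,dependent,0,20
val_syn,PYR + PYR -> VAL + CO2,abc + def > debcf + a,dependent,0,20
leu_syn,ACCOA + PYR + PYR -> LEU + CO2 + CO2,ab + cde + fgh > abgdeh + c + f,dependent,0,20
ile_syn,OAA + PYR -> ILE + CO2,abcd + efg > abfcdg + e,dependent,0,20
thr_syn,OAA -> THR,abcd > abcd,dependent,0,20
asp_syn,OAA -> ASP,abcd > abcd,dependent,0,20
met_syn,OAA + MTHF -> MET,abcd + e > abcde,dependent,0,20
lys_syn,OAA + PYR -> LYS + CO2,abcd + efg > abcdfg + e,dependent,0,20
glu_syn,AKG -> GLU,abcde > abcde,dependent,0,20
pro_syn,GLU -> PRO,abcde > abcde,dependent,0,20
phe_syn,PEP + PEP + E4P -> PHE + CO2,abc + def + ghij > defbcghij + a,dependent,0,20
tyr_syn,PEP + PEP + E4P -> TYR + CO2,abc + def + ghij > defbcghij + a,dependent,0,20
his_syn,R5P + MTHF -> HIS,abcde + f > abcdef,dependent,0,20
ala_drain,ALA -> ALAx,abc > abc,constrained,0.03,0.03
gly_drain,GLY -> GLYx,ab > ab,constrained,0.03,0.03
ser_drain,SER -> SERx,abc > abc,constrained,0.03,0.03
val_drain,VAL -> VALx,abcde > abcde,constrained,0.03,0.03
leu_drain,LEU -> LEUx,abcdef > abcdef,constrained,0.03,0.03
ile_drain,ILE -> ILEx,abcdef > abcdef,constrained,0.03,0.03
thr_drain,THR -> THRx,abcd > abcd,constrained,0.03,0.03
asp_drain,ASP -> ASPx,abcd > abcd,constrained,0.03,0.03
met_drain,MET -> METx,abcde > abcde,constrained,0.03,0.03
lys_drain,LYS -> LYSx,abcdef > abcdef,constrained,0.03,0.03
glu_drain,GLU -> GLUx,abcde > abcde,constrained,0.03,0.03
pro_drain,PRO -> PROx,abcde > abcde,constrained,0.03,0.03
phe_drain,PHE -> PHEx,abcdefghi > abcdefghi,constrained,0.03,0.03
tyr_drain,TYR -> TYRx,abcdefghi > abcdefghi,constrained,0.03,0.03
his_drain,HIS -> HISx,abcdef > abcdef,constrained,0.03,0.03
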