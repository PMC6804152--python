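id,name,formula,compound_class,subclass,sapogenin,source_herb,sugar_composition,acyl,expected_rt,reference_standard
noto-r1,notoginsenoside R1,C47H80O18,ginsenoside,PPT,PPT,NRR,Glc:2;Pen:1,,5.74,true
gins-rg1,ginsenoside Rg1,C42H72O14,ginsenoside,PPT,PPT,NRR,Glc:2,,,true
gins-re,ginsenoside Re,C48H82O18,ginsenoside,PPT,PPT,NRR,Glc:2;Rha:1,,,true
gins-rh1,ginsenoside Rh1,C36H62O9,ginsenoside,PPT,PPT,NRR,Glc:1,,,true
noto-r2,notoginsenoside R2,C41H70O13,ginsenoside,PPT,PPT,NRR,Glc:1;Pen:1,,,true
gins-re1,ginsenoside Re1,C48H82O19,ginsenoside,PPT,PPT,NRR,Glc:3,,,false
gins-re2,ginsenoside Re2,C48H82O19,ginsenoside,PPT,PPT,NRR,Glc:3,,,false
gins-re3,ginsenoside Re3,C48H82O19,ginsenoside,PPT,PPT,NRR,Glc:3,,,false
noto-r3,notoginsenoside R3,C48H82O19,ginsenoside,PPT,PPT,NRR,Glc:3,,,false
noto-r6,notoginsenoside R6,C48H82O19,ginsenoside,PPT,PPT,NRR,Glc:3,,,false
noto-m,notoginsenoside M,C48H82O19,ginsenoside,PPT,PPT,NRR,Glc:3,,,false
chiku-lm4,chikusetsusaponin LM4,C48H82O19,ginsenoside,PPT,PPT,NRR,Glc:3,,,false
gins-rb1,ginsenoside Rb1,C54H92O23,ginsenoside,PPD,PPD,NRR,Glc:4,,,true
gins-rd,ginsenoside Rd,C48H82O18,ginsenoside,PPD,PPD,NRR,Glc:3,,,true
gyp-xvii,gypenoside XVII,C48H82O18,ginsenoside,PPD,PPD,NRR,Glc:3,,,true
mal-rb1,malonylginsenoside Rb1,C57H94O26,ginsenoside,malonyl,PPD,NRR,Glc:4,malonyl:1,11.97,true
mal-rd,malonylginsenoside Rd,C51H84O21,ginsenoside,malonyl,PPD,NRR,Glc:3,malonyl:1,15.51,false
gins-ro,ginsenoside Ro,C48H76O19,ginsenoside,OA,OA,NRR,Glc:2;GlurA:1,,12.37,true
stip-r,stipuleanoside R,C53H84O23,ginsenoside,OA,OA,NRR,Glc:2;GlurA:1;Pen:1,,12.46,false
ast-iv,astragaloside IV,C41H68O14,astragaloside,cycloastragenol glycoside,cycloastragenol,AR,Glc:1;Pen:1,,12.90,true
ast-iii,astragaloside III,C41H68O14,astragaloside,cycloastragenol glycoside,cycloastragenol,AR,Glc:1;Pen:1,,13.18,true
ast-ii,astragaloside II,C43H70O15,astragaloside,cycloastragenol glycoside,cycloastragenol,AR,Glc:1;Pen:1,acetyl:1,15.26,true
ast-i,astragaloside I,C45H72O16,astragaloside,cycloastragenol glycoside,cycloastragenol,AR,Glc:1;Pen:1,acetyl:2,19.19,true
isoast-i,isoastragaloside I,C45H72O16,astragaloside,cycloastragenol glycoside,cycloastragenol,AR,Glc:1;Pen:1,acetyl:2,20.18,true
soy-i,soyasaponin I,C48H78O18,other,soyasaponin,soyasapogenol,AR,Glc:1;Rha:1;GlurA:1,,16.22,false
danshensu,danshensu,C9H10O5,phenolic_acid,simple phenolic acid,,SMRR,,,2.03,true
sal-b,salvianolic acid B,C36H30O16,phenolic_acid,salvianolic acid,,SMRR,,,6.72,true
sal-a,salvianolic acid A,C26H22O10,phenolic_acid,salvianolic acid,,SMRR,,,7.70,true
litho-a,lithospermic acid,C27H22O12,phenolic_acid,salvianolic acid,,SMRR,,,4.96,false
tan-i,tanshinone I,C18H12O3,tanshinone,diterpenoid quinone,,SMRR,,,24.14,true
cryptotan,cryptotanshinone,C19H12O3,tanshinone,diterpenoid quinone,,SMRR,,,24.21,true
tan-iia,tanshinone IIA,C19H18O3,tanshinone,diterpenoid quinone,,SMRR,,,25.96,true
formononetin,formononetin,C16H12O4,flavonoid,isoflavone,,AR,,,,true
campanulin,campanulin,C22H22O10,flavonoid,isoflavone glycoside,,AR,Glc:1,,3.80,false
caly-glc,calycosin-7-O-glucoside,C22H22O10,flavonoid,isoflavone glycoside,,AR,Glc:1,,,true
aucubin,aucubin,C15H22O9,iridoid,iridoid glycoside,,SR,Glc:1,,1.62,true
harpagide,harpagide,C15H24O10,iridoid,iridoid glycoside,,SR,Glc:1,,1.87,true
harpagoside,harpagoside,C24H30O11,iridoid,iridoid glycoside,,SR,Glc:1,,7.98,true
angoroside-c,angoroside C,C36H48O19,phenylpropanoid,phenylethanoid glycoside,,SR,Glc:1;Rha:1,,5.26,false
coum-sucrose,6-O-p-coumaroylsucrose,C21H28O13,phenylpropanoid,sucrose ester,,SR,Glc:1,,2.82,false
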