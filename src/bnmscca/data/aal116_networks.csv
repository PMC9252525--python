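roi,network
PreCG.L,SMN.L
PreCG.R,SMN.R
SFGdor.L,ATN.L
SFGdor.R,ATN.R
ORBsup.L,ATN.L
ORBsup.R,ATN.R
MFG.L,ATN.L
MFG.R,ATN.R
ORBmid.L,ATN.L
ORBmid.R,ATN.R
IFGoperc.L,ATN.L
IFGoperc.R,ATN.R
IFGtriang.L,ATN.L
IFGtriang.R,ATN.R
ORBinf.L,ATN.L
ORBinf.R,ATN.R
ROL.L,AUN.L
ROL.R,AUN.R
SMA.L,SMN.L
SMA.R,SMN.R
OLF.L,SN.L
OLF.R,SN.R
SFGmed.L,DMN.L
SFGmed.R,DMN.R
ORBsupmed.L,DMN.L
ORBsupmed.R,DMN.R
REC.L,DMN.L
REC.R,DMN.R
INS.L,AUN.L
INS.R,AUN.R
ACG.L,DMN.L
ACG.R,DMN.R
MCG.L,SN.L
MCG.R,SN.R
PCG.L,DMN.L
PCG.R,DMN.R
HIP.L,SN.L
HIP.R,SN.R
PHG.L,SN.L
PHG.R,SN.R
AMYG.L,SN.L
AMYG.R,SN.R
CAL.L,VIN.L
CAL.R,VIN.R
CUN.L,VIN.L
CUN.R,VIN.R
LING.L,VIN.L
LING.R,VIN.R
SOG.L,VIN.L
SOG.R,VIN.R
MOG.L,VIN.L
MOG.R,VIN.R
IOG.L,VIN.L
IOG.R,VIN.R
FFG.L,VIN.L
FFG.R,VIN.R
PoCG.L,SMN.L
PoCG.R,SMN.R
SPG.L,ATN.L
SPG.R,ATN.R
IPL.L,ATN.L
IPL.R,ATN.R
SMG.L,ATN.L
SMG.R,ATN.R
ANG.L,DMN.L
ANG.R,DMN.R
PCUN.L,DMN.L
PCUN.R,DMN.R
PCL.L,SMN.L
PCL.R,SMN.R
CAU.L,SN.L
CAU.R,SN.R
PUT.L,SN.L
PUT.R,SN.R
PAL.L,SN.L
PAL.R,SN.R
THA.L,SN.L
THA.R,SN.R
HES.L,AUN.L
HES.R,AUN.R
STG.L,AUN.L
STG.R,AUN.R
TPOsup.L,AUN.L
TPOsup.R,AUN.R
MTG.L,DMN.L
MTG.R,DMN.R
TPOmid.L,DMN.L
TPOmid.R,DMN.R
ITG.L,DMN.L
ITG.R,DMN.R
CEREcrus1.L,CN.L
CEREcrus1.R,CN.R
CEREcrus2.L,CN.L
CEREcrus2.R,CN.R
CERE3.L,CN.L
CERE3.R,CN.R
CERE45.L,CN.L
CERE45.R,CN.R
CERE6.L,CN.L
CERE6.R,CN.R
CERE7b.L,CN.L
CERE7b.R,CN.R
CERE8.L,CN.L
CERE8.R,CN.R
CERE9.L,CN.L
CERE9.R,CN.R
CERE10.L,CN.L
CERE10.R,CN.R
VERS12,VN
VERS3,VN
VERS45,VN
VERS6,VN
VERS7,VN
VERS8,VN
VERS9,VN
VERS10,VN
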