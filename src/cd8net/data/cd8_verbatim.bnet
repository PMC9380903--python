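targets, factors
TBET, ((IFNg | IL12s & !(IL6s | IL4 | IL10)) | TBET) & !(IL4 | GATA3 | IL6s | FOXO1)  #class: transcription_factor
IFNg, (IFNgs | IFNI | (IFNg | TBET | EOMES) & mTORC1 & !(GATA3 | TGFb)) & !IL6s | IL4 | IL10  #class: expressed_protein
GATA3, (IL2s & IL4 | EOMES | GATA3) & !(TBET | TGFb | IL6s | IFNg)  #class: transcription_factor
IL4, IL4s | (GATA3 & (IL2s | IL4) & !TBET) & !(IFNg | IL6s)  #class: expressed_protein
RORgT, IL6s & TGFb & !(TBET | FOXP3 | GATA3 | FOXO1)  #class: transcription_factor
IL10, (IL10s | EOMES | IL10 & (IFNg | IL6s | TGFb | GATA3)) & mTORC1  #class: expressed_protein
FOXP3, (IL2s | IL12s) & TGFb | FOXP3 | IL4 | FOXO1 & !(IL6s | RORgT)  #class: transcription_factor
FOXO1, (ROS | FOXO1) & !(mTORC1 | mTORC2)  #class: transcription_factor
EOMES, ROS | EOMES | IFNI & FOXO1 & !mTORC2  #class: transcription_factor
mTORC1, (aa | ROS | IL12s | IL12s | Akt) & !(mTORC2 & PD1 & IL15s)  #class: signaling
mTORC2, (GFs | ROS) & !mTORC1  #class: signaling
ROS, (Glucose | FFAs | Ceramide | EtOH) & !SOD  #class: metabolite
Akt, IFNg | IL4 | IL10 | mTORC2  #class: signaling
GLUT1, Akt & EOMES & !FOXO1  #class: expressed_protein
GranzymeB, TBET & !(GATA3 | RORgT | FOXP3 | FOXO1)  #class: expressed_protein
SOD, ROS & FOXO1 & !Ceramide  #class: expressed_protein
BCL2, FOXO1 & !ROS  #class: expressed_protein
Casp3, FasL & (ROS | Casp3) & !BCL2  #class: signaling
IL12s, IL12s
IL6s, IL6s
TGFb, TGFb
IL4s, IL4s
IL10s, IL10s
IFNgs, IFNgs
IFNI, IFNI
Glucose, Glucose
FFAs, FFAs
Ceramide, Ceramide
FasL, FasL
EtOH, EtOH
IL2s, IL2s
IL15s, IL15s
PD1, PD1
aa, aa
GFs, GFs
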