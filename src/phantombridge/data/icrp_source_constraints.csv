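# Simultaneous-use restrictions for ICRP phantom source regions.
# prohibited: regions A and B overlap anatomically and must not both carry
#   activity in one calculation (double counting).
# unusual: no overlap, but both being measured (rather than modeled) is
#   implausible, e.g. volume and surface sources of the same structure.
a,b,severity,note
Lung-tis,Lungs,prohibited,lung tissue is contained in lungs (tissue plus blood)
Remainder,Blood,prohibited,remainder tissues include their blood pools
Lung-tis,AI,prohibited,alveolar-interstitium is part of lung tissue
Lung-tis,Brchiole-b,prohibited,bronchiolar compartments lie within lung tissue
Lung-tis,Brchiole-q,prohibited,bronchiolar compartments lie within lung tissue
Lung-tis,Brchiole,prohibited,bronchiolar compartments lie within lung tissue
Lungs,AI,prohibited,alveolar-interstitium is part of the lungs
Lungs,Brchiole-b,prohibited,bronchiolar compartments lie within the lungs
Lungs,Brchiole-q,prohibited,bronchiolar compartments lie within the lungs
Lungs,Brchiole,prohibited,bronchiolar compartments lie within the lungs
C-bone-v,C-bone-s,unusual,volume and surface sources of cortical bone
ET1-wall,ET1-sur,unusual,wall tissue and surface deposit of ET1
ET2-wall,ET2-bnd,unusual,wall tissue and bound activity of ET2
ET2-wall,ET2-seq,unusual,wall tissue and sequestered activity of ET2
ET2-wall,ET2-sur,unusual,wall tissue and surface deposit of ET2
Esophag-w,Esophag-s,unusual,wall and slow-transit contents of the oesophagus
Esophag-w,Esophag-f,unusual,wall and fast-transit contents of the oesophagus
LC-wall,LC-mucosa,prohibited,mucosa is part of the left colon wall
RC-wall,RC-mucosa,prohibited,mucosa is part of the right colon wall
RS-wall,RS-mucosa,prohibited,mucosa is part of the rectosigmoid wall
SI-wall,SI-villi,prohibited,villi are part of the small intestine wall
SI-wall,SI-mucosa,prohibited,mucosa is part of the small intestine wall
ST-wall,ST-mucosa,prohibited,mucosa is part of the stomach wall
Teeth-v,Teeth-s,unusual,volume and surface sources of the teeth
T-bone-v,T-bone-s,unusual,volume and surface sources of trabecular bone
C-marrow,R-marrow,prohibited,cortical-shaft marrow overlaps active marrow
C-marrow,Y-marrow,prohibited,cortical-shaft marrow overlaps inactive marrow
T-marrow,R-marrow,prohibited,trabecular marrow overlaps active marrow
T-marrow,Y-marrow,prohibited,trabecular marrow overlaps inactive marrow
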