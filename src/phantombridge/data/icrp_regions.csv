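# ICRP adult reference phantom region registry (registry format v1).
# Masses are recorded only where this package's bundled tables print them
# (colon contents/walls, alimentary stem-cell layers, endosteum) or where an
# operation requires them: muscle and adipose carry ICRP Publication 89
# adult-male reference masses because the residual-soft-tissue apportionment
# rule splits by mass. All other masses are left unknown (blank) on purpose.
# The other_tissue_source flag marks the 41 remainder-candidate tissue sources
# used for whole-body remainder terms; it is registry data and editable.
phantom,acronym,canonical_name,role,mass_g,system,flags
ICRP,O-cavity,Oral cavity (contents),source,,alimentary,contents
ICRP,O-mucosa,Oral mucosa,both,,alimentary,other_tissue_source
ICRP,Teeth-V,Teeth (volume),source,,alimentary,other_tissue_source
ICRP,Teeth-S,Teeth (surface),source,,alimentary,other_tissue_source
ICRP,Tongue,Tongue,both,,alimentary,other_tissue_source
ICRP,Tonsils,Tonsils,both,,alimentary,other_tissue_source
ICRP,Esophag-w,Oesophagus (wall),both,,alimentary,wall;other_tissue_source
ICRP,Esophag-s,Oesophagus (slow transit contents),source,,alimentary,contents
ICRP,Esophag-f,Oesophagus (fast transit contents),source,,alimentary,contents
ICRP,ST-cont,Stomach (contents),source,,alimentary,contents
ICRP,ST-mucosa,Stomach (mucosa),source,,alimentary,other_tissue_source
ICRP,ST-wall,Stomach (wall),source,,alimentary,wall;other_tissue_source
ICRP,SI-cont,Small intestine (contents),source,,alimentary,contents
ICRP,SI-mucosa,Small intestine (mucosa),source,,alimentary,other_tissue_source
ICRP,SI-villi,Small intestine (villi),source,,alimentary,other_tissue_source
ICRP,SI-wall,Small intestine (wall),source,,alimentary,wall;other_tissue_source
ICRP,RC-cont,Right colon (contents),source,150,alimentary,contents
ICRP,RC-mucosa,Right colon (mucosa),source,,alimentary,other_tissue_source
ICRP,RC-wall,Right colon (wall),source,186.24,alimentary,wall;other_tissue_source
ICRP,LC-cont,Left colon (contents),source,75,alimentary,contents
ICRP,LC-mucosa,Left colon (mucosa),source,,alimentary,other_tissue_source
ICRP,LC-wall,Left colon (wall),source,186.24,alimentary,wall;other_tissue_source
ICRP,RS-cont,Rectosigmoid (contents),source,75,alimentary,contents
ICRP,RS-mucosa,Rectosigmoid (mucosa),source,,alimentary,other_tissue_source
ICRP,RS-wall,Rectosigmoid (wall),source,86.91,alimentary,wall;other_tissue_source
ICRP,ET1-sur,Extrathoracic region 1 (surface),source,,respiratory,
ICRP,ET1-wall,Extrathoracic region 1 (wall),source,,respiratory,wall;other_tissue_source
ICRP,ET2-sur,Extrathoracic region 2 (surface),source,,respiratory,
ICRP,ET2-bnd,Extrathoracic region 2 (bound),source,,respiratory,
ICRP,ET2-seq,Extrathoracic region 2 (sequestered),source,,respiratory,
ICRP,ET2-wall,Extrathoracic region 2 (wall),source,,respiratory,wall;other_tissue_source
ICRP,LN-ET,Lymph nodes (extrathoracic),source,,respiratory,other_tissue_source
ICRP,Bronchi,Bronchial airways,source,,respiratory,other_tissue_source
ICRP,Bronchi-b,Bronchial airways (bound),source,,respiratory,
ICRP,Bronchi-q,Bronchial airways (sequestered),source,,respiratory,
ICRP,Brchiole,Bronchiolar airways,source,,respiratory,other_tissue_source
ICRP,Brchiole-b,Bronchiolar airways (bound),source,,respiratory,
ICRP,Brchiole-q,Bronchiolar airways (sequestered),source,,respiratory,
ICRP,AI,Alveolar-interstitial region,both,,respiratory,overlap_member
ICRP,LN-Th,Lymph nodes (thoracic),both,,respiratory,other_tissue_source
ICRP,Lungs,Lungs (tissue plus blood),source,,respiratory,overlap_member
ICRP,Lung-tis,Lung tissue,both,,respiratory,overlap_member
ICRP,C-bone-v,Cortical bone (volume),source,,skeletal,other_tissue_source
ICRP,C-bone-s,Cortical bone (surface),source,,skeletal,other_tissue_source
ICRP,T-bone-v,Trabecular bone (volume),source,,skeletal,other_tissue_source
ICRP,T-bone-s,Trabecular bone (surface),source,,skeletal,other_tissue_source
ICRP,C-marrow,Marrow in cortical bone shafts,source,,skeletal,other_tissue_source
ICRP,T-marrow,Marrow in trabecular spongiosa,source,,skeletal,other_tissue_source
ICRP,R-marrow,Active (red) marrow,both,,skeletal,
ICRP,Y-marrow,Inactive (yellow) marrow,source,,skeletal,other_tissue_source
ICRP,Adipose,Adipose tissue,both,18200,other,other_tissue_source
ICRP,Adrenals,Adrenals,both,,other,
ICRP,Blood,Total body blood,source,,other,
ICRP,Brain,Brain,both,,other,
ICRP,Breast,Breast,both,,other,
ICRP,Eye-lens,Lens of the eye,both,,other,other_tissue_source
ICRP,GB-wall,Gall bladder (wall),both,,alimentary,wall
ICRP,GB-cont,Gall bladder (contents),source,,alimentary,contents
ICRP,Ht-wall,Heart (wall),both,,other,wall
ICRP,Kidneys,Kidneys,both,,other,
ICRP,Liver,Liver,both,,alimentary,
ICRP,LN-Sys,Lymph nodes (systemic),both,,other,other_tissue_source
ICRP,Muscle,Skeletal muscle,both,29000,other,other_tissue_source
ICRP,Ovaries,Ovaries,both,,other,
ICRP,Pancreas,Pancreas,both,,alimentary,
ICRP,P-gland,Pituitary gland,both,,other,other_tissue_source
ICRP,Prostate,Prostate,both,,other,other_tissue_source
ICRP,S-glands,Salivary glands,both,,alimentary,other_tissue_source
ICRP,Skin,Skin,both,,other,other_tissue_source
ICRP,Spleen,Spleen,both,,other,
ICRP,Testes,Testes,both,,other,
ICRP,Thymus,Thymus,both,,other,
ICRP,Thyroid,Thyroid,both,,other,
ICRP,Trachea,Trachea,source,,respiratory,other_tissue_source
ICRP,Ureters,Ureters,both,,other,other_tissue_source
ICRP,UB-cont,Urinary bladder (contents),source,,other,contents
ICRP,UB-wall,Urinary bladder (wall),both,,other,wall;other_tissue_source
ICRP,Uterus,Uterus,both,,other,
ICRP,Remainder,Remainder tissues,source,,other,
ICRP,Endosteum,Endosteal bone surface,target,580,skeletal,
ICRP,RC-stem,Right colon stem cell layer,target,1.35,alimentary,stem_cell_layer
ICRP,LC-stem,Left colon stem cell layer,target,1.26,alimentary,stem_cell_layer
ICRP,RS-stem,Rectosigmoid stem cell layer,target,0.759,alimentary,stem_cell_layer
ICRP,ST-stem,Stomach stem cell layer,target,0.616,alimentary,stem_cell_layer
ICRP,SI-stem,Small intestine stem cell layer,target,3.71,alimentary,stem_cell_layer
ICRP,ET1-bas,Extrathoracic region 1 basal cells,target,,respiratory,
ICRP,ET2-bas,Extrathoracic region 2 basal cells,target,,respiratory,
ICRP,Bronch-bas,Bronchial basal cells,target,,respiratory,
ICRP,Bronch-sec,Bronchial secretory cells,target,,respiratory,
ICRP,Bchiol-sec,Bronchiolar secretory cells,target,,respiratory,
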