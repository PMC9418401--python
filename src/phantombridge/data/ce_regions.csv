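# Cristy-Eckerman stylized adult phantom region registry (registry format v1).
# Masses are recorded only where this package's bundled tables print them
# (major alimentary-tract targets and osteogenic cells); all others are left
# unknown (blank) on purpose. The CE model separates wall and contents only
# where its Monte Carlo geometry did; the small intestine is a single region
# with no wall/contents separation.
phantom,acronym,canonical_name,role,mass_g,system,flags
CE,Adrenals,Adrenals,source,,other,
CE,Brain,Brain,both,,other,
CE,Breasts,Breasts,source,,other,
CE,GB-cont,Gall bladder (contents),source,,alimentary,contents
CE,ST-cont,Stomach (contents),source,,alimentary,contents
CE,ST-wall,Stomach (wall),target,158,alimentary,wall
CE,SI,Small intestine,both,677,alimentary,
CE,ULI-cont,Upper large intestine (contents),source,,alimentary,contents
CE,ULI-wall,Upper large intestine (wall),target,220,alimentary,wall
CE,LLI-cont,Lower large intestine (contents),source,,alimentary,contents
CE,LLI-wall,Lower large intestine (wall),target,167,alimentary,wall
CE,Ht-cont,Heart (contents),source,,other,contents
CE,Ht-wall,Heart (wall),both,,other,wall
CE,Kidneys,Kidneys,both,,other,
CE,Liver,Liver,both,,alimentary,
CE,Lungs,Lungs,both,,respiratory,
CE,Ovaries,Ovaries,both,,other,
CE,Pancreas,Pancreas,both,,alimentary,
CE,A-marrow,Active (red) marrow,both,,skeletal,
CE,Osteo-cells,Osteogenic cells,target,108,skeletal,
CE,Spleen,Spleen,both,,other,
CE,Testes,Testes,both,,other,
CE,Thymus,Thymus,source,,other,
CE,Thyroid,Thyroid,both,,other,
CE,UB-cont,Urinary bladder (contents),source,,other,contents
CE,UB-wall,Urinary bladder (wall),target,,other,wall
CE,Uterus,Uterus,both,,other,
CE,RST,Residual soft tissue,source,,other,
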