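# Example reference blood distribution: fraction of total-body blood residing
# in each organ's blood pool at rest. Values are representative adult
# reference-model figures shipped for demonstration and testing; users should
# supply the distribution appropriate to their reference model.
region,fraction_of_total_blood
Lung-tis,0.105
Liver,0.10
Kidneys,0.02
Spleen,0.014
Brain,0.012
Ht-wall,0.01
Muscle,0.14
Skin,0.03
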