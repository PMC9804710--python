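# Biological weighting parameters (published reference values).
rbe_nitrogen: 3.0
rbe_hydrogen: 3.0
rbe_gamma: 1.0
cbe_tumor: 3.8
cbe_skin: 2.5
cbe_normal: 1.34
blood_boron: 25.0       # ug/g
tumor_to_blood: 3.5
skin_to_blood: 1.0
brain_dose_limit: 12.5  # Gy (weighted)
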