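dc2192e05376748eb555d6492aa27d200b5d43db511b27eef862caf2ec8003d1  accessibility_janin.tsv
f171fde335449c758db051a967c3a6bc4ed530d252d6b5cc19c6685b5c77385b  aliphatic_coeffs.tsv
78bc6ef49d0b4048741ed9c00b8019c9e81f9c6786f1307177b889eb485d6607  diwv.tsv
620158f152b3bc9dbf2a0740e33d1ad5bfc01d275f43606482bd4b2200c9571e  kd_scale.tsv
07f85abae9d98702d976d0cd6015083a8a1825940263fc85f02489323207107a  kt_propensity.tsv
1ae74e7f02b5d4880a276879738f146bd2b1c0748935d20f64cba695ae6523e8  nend_rule.tsv
429b623488d697d285adc21c6074dabd01af7c62843ae7d2cf5ac33e6e6652ff  pka.tsv
70bf2a59431e71a56e3a8e37808ddd926b3233d0f8585a89287bfbd781732fd8  residue_mass.tsv
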