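c0eebfcbd4816ddc23e30ce53d4b032094b84a4aea044743be7a773b383bc487  antigenic_determinants.tsv
393a92f883204bb97d9897dab28d554a33344cef5eb512c2b78966879206f81f  composition_1qfx.tsv
0f5f5bb6d2838898441a71831efd9d7da2e029f8d155d0bae0baf9eb56cd7181  composition_3k4q.tsv
63ffc311ff55fccfd4476ad1074c95382107f79d9af9a51f5b19456d4241cefe  glycation_distances.tsv
eff31641dec8687e319c1aa7c98dec8e8cc75851a46ce7f9847987b8d7bc3305  glycation_predictions.tsv
005ccd72ef69078cd4807c8e1e1e866ee60af771e4756ddd8b1536eb6ddab7a6  sequons.tsv
276aa2a6149e045530dfef4a388ba4370911145473c179212bfb96df7ac164ff  summary_values.tsv
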