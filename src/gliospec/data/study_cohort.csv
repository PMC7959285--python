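histology,label,grade,n_samples,n_spectra
"Astrocytoma, WHO grade II (IDH-mutant)",Tumor,II,0,0
"Oligodendroglioma, WHO grade II (IDH-mutant)",Tumor,II,4,220
"Astrocytoma, WHO grade III (IDH-mutant)",Tumor,III,5,259
"Oligodendroglioma, WHO grade III (IDH-mutant)",Tumor,III,12,642
"Glioblastoma, WHO grade IV (IDH wild-type)",Tumor,IV,14,773
"Glioblastoma, WHO grade IV (IDH mutant)",Tumor,IV,3,179
Normal brain tissue,Healthy,,25,1377
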