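# Molar (base-10) extinction coefficients of human hemoglobin, converted
# from the OMLC (Prahl) compilation: eps[mm^-1 uM^-1] = eps[cm^-1 M^-1] * 1e-7
wavelength_nm,eps_HbO2,eps_Hb,units,source_tag
660,3.1996e-05,3.22657e-04,mm^-1 uM^-1 (base-10 molar),OMLC-Prahl-hemoglobin
740,4.4600e-05,1.11588e-04,mm^-1 uM^-1 (base-10 molar),OMLC-Prahl-hemoglobin
850,1.0580e-04,6.91320e-05,mm^-1 uM^-1 (base-10 molar),OMLC-Prahl-hemoglobin
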