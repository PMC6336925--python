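wavelength_nm,eps_hbo2,eps_hbr
705,298.0,1687.76
830,974.0,693.04
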