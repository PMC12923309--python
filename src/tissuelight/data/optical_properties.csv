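# tissuelight default NIR optical-property table, version 1.
# Synthetic literature-style values for the four-layer tumor model; these are
# representative NIR magnitudes (not measurements): tissue mu_a of order
# 0.001-0.05 /mm, mu_s of order 1-20 /mm, g ~ 0.9, n = 1.37, with weak
# spectral dispersion so that unloaded-tissue transport is nearly
# wavelength-flat across 808-890 nm.  All coefficients per mm.
layer,wavelength_nm,mua,mus,unit,g,n,thickness_mm
epidermis,808,0.019,22.0,per_mm,0.90,1.37,0.1
epidermis,852,0.018,21.2,per_mm,0.90,1.37,0.1
epidermis,890,0.017,20.5,per_mm,0.90,1.37,0.1
dermis,808,0.011,12.0,per_mm,0.90,1.37,2.0
dermis,852,0.0105,11.6,per_mm,0.90,1.37,2.0
dermis,890,0.010,11.3,per_mm,0.90,1.37,2.0
fat,808,0.009,10.0,per_mm,0.90,1.37,6.0
fat,852,0.0095,9.7,per_mm,0.90,1.37,6.0
fat,890,0.010,9.5,per_mm,0.90,1.37,6.0
tumor,808,0.005,9.0,per_mm,0.90,1.37,2.0
tumor,852,0.0052,8.7,per_mm,0.90,1.37,2.0
tumor,890,0.0055,8.5,per_mm,0.90,1.37,2.0
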