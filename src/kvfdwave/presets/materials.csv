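# Shear KVFD presets for prostatic tissue (rho in kg/m^3, mu in Pa,
# eta in Pa*s^alpha, alpha dimensionless).  The cancerous values are the
# normal ones scaled by the 1.2 stiffness-contrast ratio of a minimum
# clinically significant (Gleason 6) tumour, at unchanged alpha.
name,rho_kgm3,mu_pa,eta_pasa,alpha
prostate_normal,1000,3000,35.0,0.35
prostate_cancer,1000,3600,42.0,0.35
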