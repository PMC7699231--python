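abbreviation,full_name,mw,p_vap,s_w,log_kow,loq,reference_dose,rfd_basis,property_source
DBP,dibutyl phthalate,278.34,2.01e-05,1.12e-02,4.50,30.6,2,"LOAEL, endpoint: germ cell development, species: rat","HSDB/PubChem CID 3026, 25 degC"
DEHA,di(2-ethylhexyl) adipate,370.57,8.50e-07,7.80e-04,6.11,41.0,170,"NOAEL, endpoint: changes in bodyweight and liver weight, species: rat","HSDB/PubChem CID 7641, 25 degC"
DEHP,di(2-ethylhexyl) phthalate,390.56,1.42e-07,2.70e-04,7.60,32.5,3,"NOAEL, endpoint: nipple retention, species: rat","HSDB/PubChem CID 8343, 25 degC"
DEP,diethyl phthalate,222.24,2.10e-03,1.08e+00,2.42,44.0,750,"NOAEL, endpoint: decreased growth rate, species: rat","HSDB/PubChem CID 6781, 25 degC"
DIBP,di-isobutyl phthalate,278.34,4.76e-05,6.20e-03,4.11,33.1,125,"NOAEL, endpoint: nipple retention, species: rat","HSDB/PubChem CID 6782, 25 degC"
DINP,diisononyl phthalate,418.61,5.40e-07,6.10e-07,8.80,35.6,15,"NOAEL, endpoint: hepatotoxicity, species: rat","HSDB/PubChem CID 590836, 25 degC"
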