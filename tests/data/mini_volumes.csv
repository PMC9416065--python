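subject_id,scan_id,scan_ordinal,age,sex,site,protocol_id,slice_resolution_mm,vol_brain,vol_sulci,vol_cranial_space,total_volume_mm3,vol_ventricles
S1,S1-1,1,41.3,F,site1,site1-1.2,1.2,1180000,82000,158000,1420000,9100
S1,S1-2,2,42.8,F,site1,site1-1.2,1.2,1176000,83000,159000,1418000,9400
S2,S2-1,1,63.0,M,site2,site2-2.0,2.0,1220000,90000,170000,1480000,21500
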