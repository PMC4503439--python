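peak_id,precursor_mz,rt_min,fragments,sources
alpha-MG,411.21,27.6,354.85;299.19,plasma;urine;feces;liver;small_intestine;S9_liver;S9_intestine
M1,587.17,21.4,355.18;104.30,plasma;urine;feces;liver;small_intestine;S9_liver;S9_intestine
M2,587.04,25.1,531.18;411.05;354.86,plasma;urine;feces;liver;small_intestine;S9_liver;S9_intestine
M3,587.23,26.6,530.98;411.17;354.86,plasma;urine;feces;liver;small_intestine;S9_liver;S9_intestine
M4,763.21,21.0,707.15;587.06;530.99;411.23;355.10,plasma;feces;liver;small_intestine
M5,409.07,20.8,352.91;334.81;289.04,urine;feces;liver;small_intestine
M6,409.07,24.7,353.23;321.04;83.98,urine;feces;liver;small_intestine
M7,409.33,25.0,353.10,urine;feces;liver;small_intestine
M8,409.14,27.6,352.91;334.94,urine;feces;liver;small_intestine
M9,413.00,26.6,356.92,urine
M10,427.17,16.5,371.33;354.85;132.86;105.25,liver;small_intestine;feces
M11,426.85,18.2,354.97,liver;small_intestine;feces
M12,427.30,24.6,408.94;385.22;354.91;353.04;272.95,liver;small_intestine;feces
M13,427.43,26.4,371.13;341.27;299.26,liver;small_intestine;feces
M14,426.98,27.4,408.94;315.16,liver;small_intestine;feces
M15,425.04,28.2,369.19;351.10,liver;small_intestine;feces
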