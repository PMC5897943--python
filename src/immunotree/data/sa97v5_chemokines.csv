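study_id,CCL2,CCL3,CCL4,CCL5,CCL7,CCL11,CCL20,CX3CL1,CXCL14
SA97V5,28.7,14.3,27.2,13.4,38.0,36.9,30.6,32.9,-3.3
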