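tracer,roi,slope,intercept,pipeline,source
RO948,universal,13.05,-15.57,CL-SPM,Table 1
RO948,mesial_temporal,11.76,-13.08,CL-SPM,Table 1
RO948,meta_temporal,13.16,-16.19,CL-SPM,Table 1
RO948,temporo_parietal,13.05,-15.62,CL-SPM,Table 1
RO948,frontal,12.61,-13.45,CL-SPM,Table 1
FTP,universal,13.63,-15.85,CL-SPM,Table 1
FTP,mesial_temporal,10.42,-12.11,CL-SPM,Table 1
FTP,meta_temporal,12.95,-15.37,CL-SPM,Table 1
FTP,temporo_parietal,13.75,-15.92,CL-SPM,Table 1
FTP,frontal,11.61,-13.01,CL-SPM,Table 1
MK6240,universal,10.08,-10.06,CL-SPM,Table 1
MK6240,mesial_temporal,7.28,-7.01,CL-SPM,Table 1
MK6240,meta_temporal,9.36,-10.6,CL-SPM,Table 1
MK6240,temporo_parietal,9.98,-10.15,CL-SPM,Table 1
MK6240,frontal,10.05,-8.91,CL-SPM,Table 1
GTP1,universal,10.67,-11.92,CL-SPM,Table 1
GTP1,mesial_temporal,7.88,-8.75,CL-SPM,Table 1
GTP1,meta_temporal,9.60,-11.10,CL-SPM,Table 1
GTP1,temporo_parietal,10.84,-12.27,CL-SPM,Table 1
GTP1,frontal,9.41,-9.71,CL-SPM,Table 1
PM-PBB3,universal,16.73,-15.34,CL-SPM,Table 1
PM-PBB3,mesial_temporal,7.97,-7.83,CL-SPM,Table 1
PM-PBB3,meta_temporal,11.78,-11.21,CL-SPM,Table 1
PM-PBB3,temporo_parietal,16.16,-14.68,CL-SPM,Table 1
PM-PBB3,frontal,15.7,-13.18,CL-SPM,Table 1
PI2620,universal,8.45,-9.61,CL-SPM,Table 1
PI2620,mesial_temporal,6.03,-6.83,CL-SPM,Table 1
PI2620,meta_temporal,7.78,-9.33,CL-SPM,Table 1
PI2620,temporo_parietal,8.21,-9.52,CL-SPM,Table 1
PI2620,frontal,9.07,-9.01,CL-SPM,Table 1
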