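label,substrate,days_elapsed,status,failure_mechanism
PET #1,PET,30,working,none
PET #2,PET,30,working,none
PET #3,PET,30,working,minor_permeation
PET #4,PET,30,working,none
SU-8 #1,SU-8,22,failed,crack_electrode
SU-8 #2,SU-8,17,failed,crack_electrode
SU-8 #3,SU-8,8,failed,crack_wire
SU-8 #4,SU-8,7,failed,crack_wire
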