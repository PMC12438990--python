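category,include,exclude
SUD,F10-F19,
SZ,F20-F29,
BD,F30-F31,
SRD,F32;F33,
OMD,F34-F39,
AND,F40;F41;F93,
OCD,F42,
SAD,F43,
SOM,F44-F48,
ED,F50,
PD,F60-F69,
ID,F70-F79,
ODD,F80-F83,
ASD,F84,F84.2-F84.4
ADHD,F90;F98.8,
CD,F91,
AD,F94,F94.0
TD,F95,
OTHER,F51-F59;F84.2-F84.4;F88;F89;F92;F98.0-F98.6;F98.9;F99,
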