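adult_id,social_status,shell_length_mm,MS-03_a,MS-03_b,MS-26_a,MS-26_b,MS-31_a,MS-31_b,MS-34_a,MS-34_b
M20,paired,,113,119,287,295,57,57,235,238
M21,paired,,115,121,275,281,57,59,238,238
M25,solitary,,117,121,272,283,57,57,235,238
M26,solitary,,115,119,281,287,57,57,232,238
M27,paired,,115,117,277,281,57,61,235,238
M28,solitary,,115,117,275,277,57,57,238,238
M29,solitary,,113,115,275,287,57,57,235,238
M30,paired,,117,117,275,275,43,57,238,238
M31,paired,,117,117,283,287,59,61,238,244
M32,solitary,,117,117,287,295,51,51,238,238
M33,paired,,115,115,277,295,57,57,238,238
M34,solitary,,115,115,281,283,41,57,235,238
M35,solitary,,113,115,275,287,57,59,235,238
M37,solitary,,117,119,277,283,51,57,238,238
PP20,paired,,115,115,272,277,57,57,238,238
PP33,paired,,115,117,281,283,57,57,232,238
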