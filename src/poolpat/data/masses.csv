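mass_id,maternal_id,maternal_status,putative_sire_id,MS-03,MS-26,MS-31,MS-34
20,M20,paired,PP20,113;117;119,283;287;295,57;59;61,235;238;244
21,M21,paired,,115;117;121,275;281;295,57;59,238
23,NS,paired,,115;117;121,275;281;295,57;59,238
25,M25,solitary,,115;117;121,272;277;281;283,57;61,235;238
26,M26,solitary,,115;119,275;287,53;57;59;61;63,234;238;244
27,M27,paired,M30,115;117,275;277;281,43;57;61,235;238
28,M28,solitary,,113;115;119,275;277;283;287,57;61;63,232;238
29,M29,solitary,,115,ND,57,232;235;238
30,M30,paired,M27,115;117,275;281,57;59,232;238
31,M31,paired,,117,275;287,57;59,235;238;244
32,M32,solitary,,115;117;119,269;275;283;287,ND,232;235;238;244
33,M33,paired,PP33,115;117,275;277;287;295,57,235;238
34,M34,solitary,,113;115,277;281;283,41;53;57,232;235;238
35,M35,solitary,,115;117;121,275;281;287,57;59,235;238
36,NS,solitary,,115;117,277;281;283,57;59,232;238
37,M37,solitary,,ND,275;277;281;283,57;59,232;235;238;244
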