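subject_id,unit_id,group_id,occasion,week,sccs,ks2,kon
S001,U1,G1,1,0.0,54,218,16
S001,U1,G1,2,2.0,45,,
S001,U1,G1,3,4.0,37,,
S001,U1,G1,4,6.0,37,,
S001,U1,G1,5,8.0,37,247,
S002,U1,G2,1,0.0,50,259,2
S002,U1,G2,2,2.0,42,,
S002,U1,G2,3,4.0,34,,
S002,U1,G2,4,6.0,43,,
S002,U1,G2,5,8.0,43,273,
S003,U1,G3,1,0.0,55,206,26
S003,U1,G3,2,2.0,46,,
S003,U1,G3,3,4.0,39,,
S003,U1,G3,4,6.0,47,,
S003,U1,G3,5,8.0,47,252,
S004,U2,G4,1,0.0,59,289,29
S004,U2,G4,2,2.0,49,,
S004,U2,G4,3,4.0,42,,
S004,U2,G4,4,6.0,42,,
S004,U2,G4,5,8.0,42,255,
S005,U2,G5,1,0.0,56,113,17
S005,U2,G5,2,2.0,56,,
S005,U2,G5,3,4.0,48,,
S005,U2,G5,4,6.0,58,,
S005,U2,G5,5,8.0,57,107,
S006,U3,G6,1,0.0,46,454,14
S006,U3,G6,2,2.0,46,,
S006,U3,G6,3,4.0,37,,
S006,U3,G6,4,6.0,46,,
S006,U3,G6,5,8.0,47,536,
S007,U3,G7,1,0.0,42,79,45
S007,U3,G7,2,2.0,50,,
S007,U3,G7,3,4.0,58,,
S007,U3,G7,4,6.0,59,,
S007,U3,G7,5,8.0,59,0,
S008,U1,G1,1,0.0,35,371,57
S008,U1,G1,2,2.0,36,,
S008,U1,G1,3,4.0,28,,
S008,U1,G1,4,6.0,37,,
S008,U1,G1,5,8.0,36,150,
S009,U1,G2,1,0.0,43,508,66
S009,U1,G2,2,2.0,36,,
S009,U1,G2,3,4.0,27,,
S009,U1,G2,4,6.0,36,,
S009,U1,G2,5,8.0,36,595,
S010,U1,G3,1,0.0,45,405,38
S010,U1,G3,2,2.0,36,,
S010,U1,G3,3,4.0,29,,
S010,U1,G3,4,6.0,28,,
S010,U1,G3,5,8.0,28,386,
S011,U2,G4,1,0.0,40,404,35
S011,U2,G4,2,2.0,40,,
S011,U2,G4,3,4.0,31,,
S011,U2,G4,4,6.0,40,,
S011,U2,G4,5,8.0,41,293,
S012,U2,G5,1,0.0,38,120,54
S012,U2,G5,2,2.0,39,,
S012,U2,G5,3,4.0,30,,
S012,U2,G5,4,6.0,40,,
S012,U2,G5,5,8.0,38,0,
S013,U3,G6,1,0.0,27,192,22
S013,U3,G6,2,2.0,26,,
S013,U3,G6,3,4.0,27,,
S013,U3,G6,4,6.0,25,,
S013,U3,G6,5,8.0,27,300,
S014,U3,G7,1,0.0,30,269,9
S014,U3,G7,2,2.0,30,,
S014,U3,G7,3,4.0,23,,
S014,U3,G7,4,6.0,32,,
S014,U3,G7,5,8.0,32,225,
S015,U1,G1,1,0.0,28,136,13
S015,U1,G1,2,2.0,27,,
S015,U1,G1,3,4.0,19,,
S015,U1,G1,4,6.0,28,,
S015,U1,G1,5,8.0,28,264,
S016,U1,G2,1,0.0,30,468,58
S016,U1,G2,2,2.0,21,,
S016,U1,G2,3,4.0,12,,
S016,U1,G2,4,6.0,22,,
S016,U1,G2,5,8.0,22,501,
S017,U1,G3,1,0.0,20,172,79
S017,U1,G3,2,2.0,21,,
S017,U1,G3,3,4.0,13,,
S017,U1,G3,4,6.0,21,,
S017,U1,G3,5,8.0,21,78,
S018,U2,G4,1,0.0,28,474,68
S018,U2,G4,2,2.0,29,,
S018,U2,G4,3,4.0,29,,
S018,U2,G4,4,6.0,28,,
S018,U2,G4,5,8.0,29,529,
S019,U2,G5,1,0.0,26,472,48
S019,U2,G5,2,2.0,34,,
S019,U2,G5,3,4.0,41,,
S019,U2,G5,4,6.0,42,,
S019,U2,G5,5,8.0,42,270,
S020,U3,G6,1,0.0,34,356,75
S020,U3,G6,2,2.0,26,,
S020,U3,G6,3,4.0,17,,
S020,U3,G6,4,6.0,26,,
S020,U3,G6,5,8.0,26,513,
S021,U3,G7,1,0.0,32,217,68
S021,U3,G7,2,2.0,25,,
S021,U3,G7,3,4.0,18,,
S021,U3,G7,4,6.0,16,,
S021,U3,G7,5,8.0,17,244,
S022,U1,G1,1,0.0,34,343,79
S022,U1,G1,2,2.0,33,,
S022,U1,G1,3,4.0,25,,
S022,U1,G1,4,6.0,33,,
S022,U1,G1,5,8.0,33,187,
S023,U1,G2,1,0.0,29,235,35
S023,U1,G2,2,2.0,19,,
S023,U1,G2,3,4.0,13,,
S023,U1,G2,4,6.0,13,,
S023,U1,G2,5,8.0,12,166,
S024,U1,G3,1,0.0,29,247,48
S024,U1,G3,2,2.0,21,,
S024,U1,G3,3,4.0,14,,
S024,U1,G3,4,6.0,22,,
S024,U1,G3,5,8.0,22,185,
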