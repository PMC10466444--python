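concept_id,source_code,source_vocabulary,domain
2000000101,E11.9,ICD10GM,Condition
2000000102,I10.0,ICD10GM,Condition
2000000103,J44.9,ICD10GM,Condition
2000000104,K52.9,ICD10GM,Condition
2000000105,M54.5,ICD10GM,Condition
2000000106,F32.1,ICD10GM,Condition
2000000107,C34.1,ICD10GM,Condition
2000000108,N39.0,ICD10GM,Condition
2000000109,Z01.8,ICD10GM,Observation
2000000110,Z92.1,ICD10GM,Observation
2000000111,R94.3,ICD10GM,Measurement
2000000112,Z98.8,ICD10GM,Procedure
2000000113,U07.1,ICD10GM,Condition
2000000201,718-7,LOINC,Measurement
2000000202,2160-0,LOINC,Measurement
2000000203,6690-2,LOINC,Measurement
2000000204,2951-2,LOINC,Measurement
2000000205,8302-2,LOINC,Measurement
2000000206,29463-7,LOINC,Measurement
2000000207,72166-2,LOINC,Observation
2000000208,74013-4,LOINC,Observation
2000000301,5-470,OPS,Procedure
2000000302,1-632,OPS,Procedure
2000000303,8-800,OPS,Procedure
2000000304,5-511,OPS,Procedure
2000000305,3-200,OPS,Procedure
2000000306,8-930,OPS,Observation
2000000401,N02BE01,ATC,Drug
2000000402,B01AC06,ATC,Drug
2000000403,C09AA02,ATC,Drug
2000000404,A02BC01,ATC,Drug
2000000405,J01CA04,ATC,Drug
2000000406,C10AA05,ATC,Drug
2000000407,N05BA06,ATC,Drug
2000000408,R03AC02,ATC,Drug
2000000501,I,STAGE,Observation
2000000502,II,STAGE,Observation
2000000503,III,STAGE,Observation
2000000504,IV,STAGE,Observation
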