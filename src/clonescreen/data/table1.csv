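# wells_sorted=192
# clones_recovered=37
clone_id,survived_expansion,pcr_outcome,pcr_length,digest_outcome,sequencing,karyotype,note
clone_01,true,EXPECTED_SIZE,314,DOUBLE_BAND,NOT_PERFORMED,NOT_PERFORMED,
clone_02,false,NOT_TESTED,,NOT_TESTED,NOT_PERFORMED,NOT_PERFORMED,did not survive passaging
clone_03,false,NOT_TESTED,,NOT_TESTED,NOT_PERFORMED,NOT_PERFORMED,did not survive passaging
clone_04,true,EXPECTED_SIZE,314,LOWER_BAND,NOT_PERFORMED,NOT_PERFORMED,
clone_05,true,EXPECTED_SIZE,314,UNDIGESTED,ISOGENIC_CONFIRMED,ABNORMAL,chromosome 4 deletion
clone_06,true,NO_PRODUCT,,NOT_TESTED,NOT_PERFORMED,NOT_PERFORMED,
clone_07,true,EXPECTED_SIZE,314,UNDIGESTED,NOT_PERFORMED,NOT_PERFORMED,
clone_08,true,EXPECTED_SIZE,314,DOUBLE_BAND,NOT_PERFORMED,NOT_PERFORMED,
clone_09,true,EXPECTED_SIZE,314,DOUBLE_BAND,NOT_PERFORMED,NOT_PERFORMED,
clone_10,true,EXPECTED_SIZE,314,DOUBLE_BAND,NOT_PERFORMED,NOT_PERFORMED,
clone_11,true,EXPECTED_SIZE,314,UNDIGESTED,NOT_PERFORMED,NOT_PERFORMED,
clone_12,true,EXPECTED_SIZE,314,UNDIGESTED,NOT_PERFORMED,NOT_PERFORMED,
clone_13,true,EXPECTED_SIZE,314,UNDIGESTED,ISOGENIC_CONFIRMED,NORMAL,
clone_14,true,SHIFTED,416,NOT_TESTED,INSERTION_ERROR,NOT_PERFORMED,102 bp insertion
clone_15,true,EXPECTED_SIZE,314,UNDIGESTED,NOT_PERFORMED,NOT_PERFORMED,
clone_16,true,EXPECTED_SIZE,314,DOUBLE_BAND,NOT_PERFORMED,NOT_PERFORMED,
clone_17,true,NO_PRODUCT,,NOT_TESTED,INSERTION_ERROR,NOT_PERFORMED,102 bp insertion
clone_18,true,EXPECTED_SIZE,314,DOUBLE_BAND,NOT_PERFORMED,NOT_PERFORMED,
clone_19,true,EXPECTED_SIZE,314,UNDIGESTED,ISOGENIC_CONFIRMED,NOT_PERFORMED,
clone_20,true,EXPECTED_SIZE,314,DOUBLE_BAND,NOT_EDITED,NOT_PERFORMED,heterozygous mutation retained
clone_21,true,EXPECTED_SIZE,314,LOWER_BAND,NOT_PERFORMED,NOT_PERFORMED,
clone_22,true,EXPECTED_SIZE,314,UNDIGESTED,NOT_PERFORMED,NOT_PERFORMED,
clone_23,true,EXPECTED_SIZE,314,LOWER_BAND,NOT_PERFORMED,NOT_PERFORMED,
clone_24,true,EXPECTED_SIZE,314,DOUBLE_BAND,NOT_PERFORMED,NOT_PERFORMED,
clone_25,true,EXPECTED_SIZE,314,UNDIGESTED,NOT_PERFORMED,NOT_PERFORMED,
clone_26,true,EXPECTED_SIZE,314,DOUBLE_BAND,NOT_PERFORMED,NOT_PERFORMED,
clone_27,true,EXPECTED_SIZE,314,UNDIGESTED,NOT_PERFORMED,NOT_PERFORMED,
clone_28,true,EXPECTED_SIZE,314,DOUBLE_BAND,NOT_PERFORMED,NOT_PERFORMED,
clone_29,true,EXPECTED_SIZE,314,UNDIGESTED,ISOGENIC_CONFIRMED,NOT_PERFORMED,
clone_30,true,EXPECTED_SIZE,314,DOUBLE_BAND,NOT_PERFORMED,NOT_PERFORMED,
clone_31,true,EXPECTED_SIZE,314,LOWER_BAND,NOT_PERFORMED,NOT_PERFORMED,
clone_32,true,EXPECTED_SIZE,314,LOWER_BAND,NOT_PERFORMED,NOT_PERFORMED,
clone_33,true,EXPECTED_SIZE,314,UNDIGESTED,ISOGENIC_CONFIRMED,NORMAL,
clone_34,true,EXPECTED_SIZE,314,DOUBLE_BAND,NOT_PERFORMED,NOT_PERFORMED,
clone_35,false,NOT_TESTED,,NOT_TESTED,NOT_PERFORMED,NOT_PERFORMED,did not survive passaging
clone_36,true,EXPECTED_SIZE,314,DOUBLE_BAND,NOT_PERFORMED,NOT_PERFORMED,
clone_37,true,EXPECTED_SIZE,314,DOUBLE_BAND,NOT_PERFORMED,NOT_PERFORMED,
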