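row_id,individual_id,ripening_date,genotype,hue_mean,hue_sd,phenotype
P1,GxC_10-16,2025-11-06,C/T,72.3,0.7,Orange
P2,GxC_5-17,2025-11-06,C/T,73.4,0.4,Orange
P3,GxC_7-10,2025-05-30,C/T,73.5,1.4,Orange
P4,GxC_5-9,2025-06-06,C/T,73.8,0.3,Orange
P5,GxC_7-11,2025-11-06,C/T,74.3,0.5,Orange
P6,GxC_7-5,2025-11-06,C/T,74.3,0.1,Orange
P7,GxC_5-13,2025-06-06,C/T,74.7,0.5,Orange
P8,GxC_11-14,2025-11-06,C/T,75.1,0.3,Orange
P9,GxC_11-1,2025-11-06,C/T,75.3,0.5,Orange
P10,GxC_4-4,2025-06-06,C/T,75.4,0.6,Orange
P11,GxC_7-14,2025-06-06,C/T,75.6,0.4,Orange
P12,GxC_4-17,2025-05-27,C/T,75.9,3.2,Orange
P13,GxC_3-7,2025-11-06,C/T,76.0,0.3,Orange
P14,GxC_11-3,2025-11-06,C/T,76.0,0.3,Orange
P15,GxC_7-16,2025-06-06,C/T,76.0,0.3,Orange
P16,GxC_6-15,2025-06-06,C/T,76.1,1.1,Orange
P17,GxC_6-18,2025-05-30,C/T,76.1,1.7,Orange
P18,GxC_8-19,2025-05-30,C/T,76.4,2.1,Orange
P19,GxC_2-6,2025-05-30,C/T,76.7,1.8,Orange
P20,GxC_1-9,2025-05-30,C/T,76.9,1.4,Orange
P21,GxC_9-19,2025-06-06,C/T,76.9,0.2,Orange
P22,GxC_2-8,2025-06-06,C/C,85.1,0.4,Yellow
P23,GxC_5-7,2025-06-06,C/C,85.5,0.5,Yellow
P24,GxC_2-7,2025-06-06,C/C,86.3,0.3,Yellow
P25,GxC_7-15,2025-06-06,C/C,86.5,1.5,Yellow
P26,GxC_8-2,2025-05-30,C/C,86.6,1.6,Yellow
P27,GxC_2-2,2025-06-06,C/C,86.8,0.8,Yellow
P28,GxC_10-3,2025-05-30,C/C,86.9,0.4,Yellow
P29,GxC_11-10,2025-06-06,C/C,87.0,0.5,Yellow
P30,GxC_11-19,2025-06-06,C/C,87.9,0.2,Yellow
P31,GxC_9-16,2025-06-06,C/C,88.0,0.3,Yellow
P32,GxC_2-10,2025-06-06,C/C,88.1,0.2,Yellow
P33,GxC_3-10,2025-06-06,C/C,88.1,0.4,Yellow
P34,GxC_1-2,2025-05-30,C/C,88.9,1.4,Yellow
P35,GxC_7-17,2025-05-30,C/C,89.0,1.3,Yellow
P36,GxC_4-6,2025-11-06,C/C,89.3,1.1,Yellow
P37,GxC_6-10,2025-06-06,C/C,90.2,0.6,Yellow
P38,GxC_4-11,2025-05-30,C/C,90.3,0.7,Yellow
P39,GxC_8-8,2025-05-30,C/C,90.9,1.9,Yellow
P40,GxC_2-11,2025-06-06,C/C,92.4,0.8,Yellow
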