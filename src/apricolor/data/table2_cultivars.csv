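row_id,individual_id,ripening_date,genotype,hue_mean,hue_sd,phenotype
C1,Totem,2025-05-22,C/T,51.8,6.6,Orange
C2,Cheyenne,2025-06-06,C/T,63.0,1.3,Orange
C3,Fuego,2025-05-27,C/T,63.5,5.7,Orange
C4,Playa Cot,2025-06-12,C/T,64.4,0.9,Orange
C5,Pricia,2025-05-30,C/T,65.5,2.6,Orange
C6,Cebas Red,2025-05-12,T/T,65.9,2.0,Orange
C7,Sunglo,2025-07-03,C/T,66.0,0.8,Orange
C8,Micaelo,2025-06-16,C/T,66.5,1.1,Orange
C9,Orange Ruby,2025-06-12,C/T,66.9,0.5,Orange
C10,Flopria,2025-06-06,T/T,66.9,1.2,Orange
C11,Toñi,2025-06-06,C/T,67.3,1.0,Orange
C12,L3-11,2025-05-22,C/T,67.5,1.2,Orange
C13,Colorado,2025-05-16,C/T,67.9,2.1,Orange
C14,Rosa,2025-06-06,C/T,68.0,0.4,Orange
C15,Palsteyn,2025-06-06,C/C,68.3,1.1,Orange
C16,Bergarouge,2025-07-03,C/T,68.9,1.1,Orange
C17,Goldrich,2025-06-11,C/T,68.9,1.0,Orange
C18,Monster Cot,2025-06-12,C/T,69.2,0.6,Orange
C19,Selene,2025-06-06,C/T,69.3,1.1,Orange
C20,Tardorange,2025-06-19,C/T,69.3,1.6,Orange
C21,Lady Cot,2025-06-16,C/T,69.5,1.1,Orange
C22,Harogem,2025-06-19,C/T,69.5,2.1,Orange
C23,Rubisco,2025-05-30,C/T,69.8,2.2,Orange
C24,Maya Cot,2025-05-20,C/T,69.8,2.1,Orange
C25,Cebas57,2025-05-20,T/T,70.0,0.7,Orange
C26,Mirlo Blanco,2025-05-20,C/T,70.1,1.5,Orange
C27,Magic Cot,2025-05-27,T/T,70.3,2.8,Orange
C28,Orange Red,2025-06-11,C/T,70.3,0.4,Orange
C29,11_1,2025-06-19,C/T,71.1,0.5,Orange
C30,Tsunami,2025-05-30,T/T,71.1,0.8,Orange
C31,Murciana,2025-06-12,C/T,71.2,1.1,Orange
C32,Lilly Cot,2025-05-22,C/T,71.9,0.6,Orange
C33,Sublime,2025-05-30,C/T,72.6,2.8,Orange
C34,Valorange,2025-06-06,C/T,72.6,1.0,Orange
C35,Mirlo Naranja,2025-05-16,C/T,72.8,2.2,Orange
C36,Maravilla,2025-06-06,C/T,72.8,0.3,Orange
C37,Deseo,2025-06-19,C/T,72.9,0.2,Orange
C38,Estrella,2025-05-30,T/T,73.1,2.4,Orange
C39,Mirlo Rojo,2025-05-27,C/T,73.5,2.2,Orange
C40,Micado,2025-05-20,C/T,73.9,2.2,Orange
C41,Tyrinthos,2025-05-27,C/C,74.5,1.1,Orange
C42,Lito,2025-06-19,C/C,75.7,2.4,Light Orange
C43,San Castrese,2025-06-12,C/C,78.1,0.2,Light Orange
C44,Bebeco,2025-06-12,C/C,78.5,0.2,Light Orange
C45,Rojo Pasión,2025-05-30,C/T,79.4,1.7,Light Orange
C46,Bergeron,2025-06-27,C/C,79.5,1.8,Light Orange
C47,906-12,2025-05-30,C/T,79.7,2.2,Light Orange
C48,Helena,2025-07-03,C/C,83.8,0.8,Yellow
C49,Canino,2025-05-30,C/C,85.3,1.6,Yellow
C50,Real Fino,2025-06-19,C/C,87.4,2.8,Yellow
C51,Mauricio,2025-05-29,C/C,87.6,1.4,Yellow
C52,Dorada,2025-07-03,C/C,88.9,0.8,Yellow
C53,Capricho,2025-06-12,C/C,90.0,0.7,Yellow
C54,Pepito del Rubio,2025-06-12,C/C,90.0,0.2,Yellow
C55,Moniqui,2025-06-16,C/C,90.2,0.7,Yellow
C56,Currot,2025-05-20,C/C,90.6,3.0,Yellow
C57,Guillermos,2025-06-12,C/C,90.9,0.4,Yellow
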