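label,blocks,exclusions
"Mental and behavioural disorders",F00-F99,
"Neoplasms",C00-D48,
"Diseases of the circulatory system",I00-I99,
"External causes/injuries except intentional self-harm",S00-T98;V01-Y98,X60-X84
"Diseases of the musculoskeletal system and connective tissue",M00-M99,
"Intentional self-harm",X60-X84,
"Diseases of the nervous system",G00-G99,
"Diseases of the digestive system",K00-K93,
"Symptoms, signs and abnormal clinical and laboratory findings, not elsewhere classified",R00-R99,
"Pregnancy, childbirth and the puerperium",O00-O99,
"Diseases of the respiratory system",J00-J99,
"Endocrine, nutritional and metabolic diseases",E00-E99,
"Diseases of the genitourinary system",N00-N99,
"Diseases of the eye and adnexa",H00-H59,
"Diseases of the ear and mastoid process",H60-H95,
"Certain infectious and parasitic diseases",A00-B99,
"Diseases of the skin and subcutaneous tissue",L00-L99,
"Congenital malformations, deformations and chromosomal abnormalities",Q00-Q99,
"Diseases of the blood and blood-forming organs and certain disorders involving the immune mechanism",D50-D89,
"Factors influencing health status and contact with health services",Z00-Z99,
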