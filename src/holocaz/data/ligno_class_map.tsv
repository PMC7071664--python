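family	roles	lignocellulolytic_default	most_common_activity	scope	provenance
GH1	cellulase_betaglucosidase,hemicellulase	true	beta-glucosidase	both	text
GH3	cellulase_betaglucosidase,hemicellulase	true	beta-glucosidase	both	text
GH5	cellulase_endo,hemicellulase	true	endoglucanase	both	text
GH6	cellulase_endo	true	endoglucanase	microbiota	text
GH8	cellulase_endo,hemicellulase	true	endoglucanase	microbiota	text
GH9	cellulase_endo	true	endoglucanase	both	text
GH44	cellulase_endo	true	endoglucanase	microbiota	text
GH48	cellulase_endo	true	endoglucanase	microbiota	text
GH74	cellulase_endo	true	xyloglucanase	microbiota	text
GH94	cellulase_phosphorylase	true	cellobiose phosphorylase	microbiota	text
GH116	cellulase_betaglucosidase	true	beta-glucosidase	microbiota	text
AA10	cellulase_lpmo	true	lytic polysaccharide monooxygenase	microbiota	text
GH2	hemicellulase	true	beta-mannosidase	both	curated
GH10	hemicellulase	true	endo-1,4-beta-xylanase	microbiota	curated
GH11	hemicellulase	true	endo-1,4-beta-xylanase	microbiota	curated
GH16	hemicellulase	true	licheninase	both	text
GH26	hemicellulase	true	beta-mannanase	microbiota	curated
GH27	hemicellulase	true	alpha-galactosidase	microbiota	curated
GH29	hemicellulase	true	alpha-fucosidase	microbiota	curated
GH30	hemicellulase	true	glucuronoxylanase	both	text
GH31	hemicellulase	true	alpha-xylosidase	both	curated
GH35	hemicellulase	true	beta-galactosidase	microbiota	curated
GH36	hemicellulase	true	alpha-galactosidase	microbiota	curated
GH39	hemicellulase	true	beta-xylosidase	microbiota	curated
GH42	hemicellulase	true	beta-galactosidase	microbiota	curated
GH43	hemicellulase	true	arabinoxylanase	both	text
GH51	hemicellulase	true	alpha-arabinofuranosidase	microbiota	curated
GH53	hemicellulase	true	endo-beta-1,4-galactanase	microbiota	curated
GH54	hemicellulase	true	alpha-arabinofuranosidase	microbiota	curated
GH67	hemicellulase	true	alpha-glucuronidase	microbiota	curated
GH78	hemicellulase	true	alpha-rhamnosidase	microbiota	curated
GH113	hemicellulase	true	beta-mannanase	microbiota	curated
GH115	hemicellulase	true	xylan alpha-glucuronidase	microbiota	curated
GH130	hemicellulase	true	beta-mannoside phosphorylase	microbiota	curated
CE1	hemicellulase	true	acetyl xylan esterase	microbiota	curated
CE2	hemicellulase	true	acetyl xylan esterase	microbiota	curated
CE3	hemicellulase	true	acetyl xylan esterase	microbiota	curated
CE4	hemicellulase	true	acetyl xylan esterase	microbiota	curated
CE5	hemicellulase	true	acetyl xylan esterase	microbiota	curated
CE6	hemicellulase	true	acetyl xylan esterase	microbiota	curated
CE7	hemicellulase	true	acetyl xylan esterase	microbiota	curated
CE15	hemicellulase	true	glucuronoyl esterase	microbiota	curated
AA1	lme_laccase	true	laccase	both	text
AA3	lme_cdh	true	cellobiose dehydrogenase	both	text
GH38	hemicellulase	true	alpha-mannosidase	host	text
GH47	hemicellulase	true	alpha-mannosidase	host	text
AA15	cellulase_lpmo	true	lytic polysaccharide monooxygenase	host	text
AA2	lme_peroxidase	true	manganese peroxidase	extended	text
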