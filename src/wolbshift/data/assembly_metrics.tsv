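host_species	n_contigs	span	n50	longest	gc	busco_complete	busco_missing	n_cds	mean_protein_length	n_rrna	n_trna
Brenthis hecate	1	1416212	1416212	1416212	0.340	99.8	0.2	1350	308.82	3	37
Colias alfacariensis	1	1464674	1464674	1464674	0.341	99.5	0.2	1420	303.80	3	37
Colias hyale	1	1652361	1652361	1652361	0.340	99.4	0.3	1546	311.90	3	35
Erebia ligea EE_932	2	1615307	1320503	1320503	0.341	99.4	0.3	1566	300.95	3	35
Erebia ligea EL_949	9	1472687	738288	738288	0.340	98.3	0.3	1437	292.17	3	36
Gonepteryx cleopatra	1	1419660	1419660	1419660	0.340	99.4	0.6	1331	312.94	3	35
Iphiclides podalirius	1	1315434	1315434	1315434	0.340	99.5	0.2	1300	294.04	3	35
Iphiclides feisthamelii	2	1357406	1271026	1271026	0.340	98.4	0.5	1273	309.42	3	36
Lasiommata petropolitana	1	1466526	1466526	1466526	0.341	99.7	0.3	1383	314.63	3	36
Polyommatus eros	1	1567905	1567905	1567905	0.341	99.4	0.3	1437	320.78	3	36
Pontia edusa	2	1315265	1268042	1268042	0.339	99.7	0.3	1204	320.01	3	35
Thymelicus acteon	7	1926985	552656	664073	0.341	96.9	2.8	1917	292.85	3	34
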