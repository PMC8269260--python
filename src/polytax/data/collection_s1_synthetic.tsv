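# SYNTHETIC stand-in for the 43-isolate chicken gut culture collection table.
# The collection-level facts (43 species; phyla Firmicutes 33, Bacteroidetes 4,
# Actinobacteria 4, Proteobacteria 2; 19 families; Lactobacillaceae 14,
# Enterococcaceae 6; seven isolates with best-hit 16S identity <= 98.7%, at
# their published identities; the nine synthetic-community members) are real
# and constrain this table exactly. Row-level details of the remaining known
# species (which species, and their best-hit identities > 98.7%) are invented
# placeholders chosen from taxa plausible in the chicken gut.
isolate_id	species_name	genus	family	phylum	best_hit_identity	is_syn_member
Cla-CZ-54	Gallibacter intestinalis	Gallibacter	Eubacteriaceae	Firmicutes	93.3	0
Cla-CZ-119	Gallalistipes aquisgranensis	Gallalistipes	Rikenellaceae	Bacteroidetes	92.5	0
Cla-CZ-245	Gemmiger gallinarum	Gemmiger	Oscillospiraceae	Firmicutes	96.2	0
Cla-CZ-62	Olsenella gallinarum	Olsenella	Atopobiaceae	Actinobacteria	96.6	0
Cla-CZ-98	Pseudoflavonifractor gallinarum	Pseudoflavonifractor	Oscillospiraceae	Firmicutes	98.2	0
Cla-CZ-49	Ructibacterium gallinarum	Ructibacterium	Oscillospiraceae	Firmicutes	89.7	0
Cla-CZ-80	Sellimonas monacensis	Sellimonas	Lachnospiraceae	Firmicutes	94.4	0
Cla-CZ-1	Escherichia sp.	Escherichia	Enterobacteriaceae	Proteobacteria	99.9	1
Cla-CZ-02	Bifidobacterium pullorum	Bifidobacterium	Bifidobacteriaceae	Actinobacteria	99.6	1
Cla-CZ-03	Alistipes onderdonkii	Alistipes	Rikenellaceae	Bacteroidetes	99.5	1
Cla-CZ-04	Phocaeicola dorei	Phocaeicola	Bacteroidaceae	Bacteroidetes	99.7	1
Cla-CZ-05	Lactobacillus crispatus	Lactobacillus	Lactobacillaceae	Firmicutes	99.8	1
Cla-CZ-06	Limosilactobacillus oris	Limosilactobacillus	Lactobacillaceae	Firmicutes	99.4	1
Cla-CZ-07	Ligilactobacillus salivarius	Ligilactobacillus	Lactobacillaceae	Firmicutes	99.6	1
Cla-CZ-08	Megamonas funiformis	Megamonas	Selenomonadaceae	Firmicutes	99.3	1
Cla-CZ-09	Anaerotignum lactatifermentans	Anaerotignum	Lachnospiraceae	Firmicutes	99.2	1
Cla-CZ-10	Lactobacillus gallinarum	Lactobacillus	Lactobacillaceae	Firmicutes	99.7	0
Cla-CZ-11	Lactobacillus helveticus	Lactobacillus	Lactobacillaceae	Firmicutes	99.5	0
Cla-CZ-12	Lactobacillus amylovorus	Lactobacillus	Lactobacillaceae	Firmicutes	99.9	0
Cla-CZ-13	Lactobacillus johnsonii	Lactobacillus	Lactobacillaceae	Firmicutes	99.6	0
Cla-CZ-14	Limosilactobacillus reuteri	Limosilactobacillus	Lactobacillaceae	Firmicutes	99.8	0
Cla-CZ-15	Limosilactobacillus vaginalis	Limosilactobacillus	Lactobacillaceae	Firmicutes	99.3	0
Cla-CZ-16	Ligilactobacillus agilis	Ligilactobacillus	Lactobacillaceae	Firmicutes	99.4	0
Cla-CZ-17	Ligilactobacillus aviarius	Ligilactobacillus	Lactobacillaceae	Firmicutes	99.2	0
Cla-CZ-18	Lactiplantibacillus plantarum	Lactiplantibacillus	Lactobacillaceae	Firmicutes	99.9	0
Cla-CZ-19	Lacticaseibacillus paracasei	Lacticaseibacillus	Lactobacillaceae	Firmicutes	99.7	0
Cla-CZ-20	Pediococcus acidilactici	Pediococcus	Lactobacillaceae	Firmicutes	99.8	0
Cla-CZ-21	Enterococcus faecalis	Enterococcus	Enterococcaceae	Firmicutes	99.9	0
Cla-CZ-22	Enterococcus faecium	Enterococcus	Enterococcaceae	Firmicutes	99.8	0
Cla-CZ-23	Enterococcus cecorum	Enterococcus	Enterococcaceae	Firmicutes	99.6	0
Cla-CZ-24	Enterococcus hirae	Enterococcus	Enterococcaceae	Firmicutes	99.7	0
Cla-CZ-25	Enterococcus durans	Enterococcus	Enterococcaceae	Firmicutes	99.5	0
Cla-CZ-26	Enterococcus avium	Enterococcus	Enterococcaceae	Firmicutes	99.4	0
Cla-CZ-27	Erysipelatoclostridium ramosum	Erysipelatoclostridium	Erysipelotrichaceae	Firmicutes	99.3	0
Cla-CZ-28	Faecalicoccus pleomorphus	Faecalicoccus	Erysipelotrichaceae	Firmicutes	99.1	0
Cla-CZ-29	Clostridium perfringens	Clostridium	Clostridiaceae	Firmicutes	99.9	0
Cla-CZ-30	Clostridium paraputrificum	Clostridium	Clostridiaceae	Firmicutes	99.5	0
Cla-CZ-31	Bacillus subtilis	Bacillus	Bacillaceae	Firmicutes	99.8	0
Cla-CZ-32	Romboutsia lituseburensis	Romboutsia	Peptostreptococcaceae	Firmicutes	99.0	0
Cla-CZ-33	Parabacteroides distasonis	Parabacteroides	Tannerellaceae	Bacteroidetes	99.7	0
Cla-CZ-34	Collinsella aerofaciens	Collinsella	Coriobacteriaceae	Actinobacteria	99.5	0
Cla-CZ-35	Eggerthella lenta	Eggerthella	Eggerthellaceae	Actinobacteria	99.6	0
Cla-CZ-36	Sutterella wadsworthensis	Sutterella	Sutterellaceae	Proteobacteria	99.3	0
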