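# Phyletic pattern of the omega intron (mitochondrial 21S/LSU rRNA) and its
# homing endonuclease gene (HEG) across 29 strains of the Saccharomyces
# complex. States: 1 = present, 0 = absent; the HEG character is only
# defined within intron-containing strains, so intron-absent rows carry NA.
#
# Totals (29 strains; 22 intron-containing; HEG scored on those 22) and the
# states of the strains discussed by name in the study's main text
# (S. cerevisiae 288C/YJM789 intron+HEG, No7 intron-absent; T. delbrueckii
# intron + disrupted HEG; T. pretoriensis and the other Torulaspora species
# intron without HEG; K. thermotolerans and L. mirantina intron+HEG) are as
# published. The remaining strain names and their HEG states are a
# plausible reconstruction consistent with those published constraints, not
# a transcription of the original figure.
taxon	intron	heg
S_cerevisiae_288C	1	1
S_cerevisiae_YJM789	1	1
S_cerevisiae_No7	0	NA
S_paradoxus_CBS432	1	1
S_cariocanus_CBS7994	1	1
S_mikatae_IFO1815	1	1
S_kudriavzevii_IFO1802	1	1
S_bayanus_CBS380	0	NA
S_pastorianus_CBS1538	0	NA
T_delbrueckii_CBS1146	1	1
T_delbrueckii_CBS3003	1	1
T_delbrueckii_CBS5448	1	1
T_pretoriensis_CBS2187	1	0
T_pretoriensis_CBS5080	1	0
T_globosa_CBS764	1	0
T_globosa_CBS2947	1	0
T_globosa_CBS5590	1	0
T_microellipsoides_CBS427	1	0
T_microellipsoides_CBS6641	1	0
K_thermotolerans_CBS6340	1	1
L_mirantina_CBS11717	1	1
N_bacillisporus_CBS7720	1	0
C_castellii_CBS4332	1	0
Kaz_africana_CBS2517	1	0
V_polyspora_DSM70294	1	1
Kaz_servazzii_CBS4311	0	NA
Naum_castellii_CBS4309	0	NA
Tet_phaffii_CBS4417	0	NA
Z_rouxii_CBS732	0	NA
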