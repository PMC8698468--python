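biotype	category
protein_coding	protein coding
lncRNA	lncRNA
lincRNA	lncRNA
antisense	lncRNA
sense_intronic	lncRNA
sense_overlapping	lncRNA
3prime_overlapping_ncRNA	lncRNA
bidirectional_promoter_lncRNA	lncRNA
macro_lncRNA	lncRNA
non_coding	lncRNA
miRNA	pre-miRNA
misc_RNA	miscellaneous RNA
snRNA	snRNA
snoRNA	snoRNA
scaRNA	scaRNA
rRNA	rRNA
rRNA_pseudogene	rRNA
Mt_rRNA	rRNA
tRNA	tRNA
Mt_tRNA	tRNA
vault_RNA	other RNA
vaultRNA	other RNA
ribozyme	other RNA
sRNA	other RNA
processed_pseudogene	other RNA
unprocessed_pseudogene	other RNA
transcribed_processed_pseudogene	other RNA
transcribed_unprocessed_pseudogene	other RNA
transcribed_unitary_pseudogene	other RNA
translated_processed_pseudogene	other RNA
translated_unprocessed_pseudogene	other RNA
unitary_pseudogene	other RNA
polymorphic_pseudogene	other RNA
pseudogene	other RNA
IG_C_pseudogene	other RNA
IG_J_pseudogene	other RNA
IG_V_pseudogene	other RNA
IG_pseudogene	other RNA
TR_J_pseudogene	other RNA
TR_V_pseudogene	other RNA
IG_C_gene	other RNA
IG_D_gene	other RNA
IG_J_gene	other RNA
IG_V_gene	other RNA
TR_C_gene	other RNA
TR_D_gene	other RNA
TR_J_gene	other RNA
TR_V_gene	other RNA
circRNA	circRNA
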