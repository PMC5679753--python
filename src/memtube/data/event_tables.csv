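label,n_events,n_positive,provenance,description
shigella_wt,23,13,paper_fixture,Shigella-induced mitochondrial constrictions in wild-type cells that led to fission
shigella_drp1_crispr,50,0,paper_fixture,Shigella-induced constrictions in DRP1 CRISPR-knockout cells
shigella_drp1_sirna,19,0,paper_fixture,Shigella-induced constrictions in DRP1-siRNA-treated cells
shigella_mff_sirna,13,1,paper_fixture,Shigella-induced constrictions in MFF-siRNA-treated cells
unstimulated,19,0,paper_fixture,non-stimulated mitochondria followed 10-150 min (scored fissions within 5 min windows)
afm_wt_methods,18,16,paper_fixture,AFM touchdowns with visible matrix reduction that led to fission (wild type; methods counts)
afm_drp1_methods,32,8,paper_fixture,AFM touchdowns leading to fission in DRP1-siRNA-treated cells (methods counts)
afm_cytd_methods,17,16,paper_fixture,AFM touchdowns leading to fission in cytochalasin-D-treated cells
afm_wt_maintext,41,36,paper_fixture,AFM successful approaches that led to fission (wild type; main-text counts)
afm_drp1_maintext,41,10,paper_fixture,AFM force applications leading to fission in DRP1-deficient cells (main-text counts)
vinyl_scrambled,84,67,paper_fixture,scrambled-siRNA cells on vinyl-record grooves with a divided mitochondrial network
vinyl_drp1_sirna,72,10,paper_fixture,DRP1-siRNA cells on vinyl grooves with a divided network
vinyl_mff_sirna,120,46,paper_fixture,MFF-siRNA cells on vinyl grooves with a divided network
vinyl_atl1_k80a,38,34,paper_fixture,ATL1-K80A-overexpressing cells on vinyl grooves with a divided network
vinyl_climp63,21,18,paper_fixture,CLIMP-63-overexpressing cells on vinyl grooves with a divided network
vinyl_wt_crispr,90,77,paper_fixture,wild-type cells on vinyl grooves with a divided network (CRISPR comparison set)
vinyl_drp1_crispr,88,36,paper_fixture,DRP1 CRISPR-knockout cells on vinyl grooves with a divided network
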