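Activated_B_cell	synthetic marker set	Activated_B_cell.M01	Activated_B_cell.M02	Activated_B_cell.M03	Activated_B_cell.M04	Activated_B_cell.M05	Activated_B_cell.M06	Activated_B_cell.M07	Activated_B_cell.M08	Activated_B_cell.M09	Activated_B_cell.M10
Activated_CD4_T_cell	synthetic marker set	Activated_CD4_T_cell.M01	Activated_CD4_T_cell.M02	Activated_CD4_T_cell.M03	Activated_CD4_T_cell.M04	Activated_CD4_T_cell.M05	Activated_CD4_T_cell.M06	Activated_CD4_T_cell.M07	Activated_CD4_T_cell.M08	Activated_CD4_T_cell.M09	Activated_CD4_T_cell.M10
Activated_CD8_T_cell	synthetic marker set	Activated_CD8_T_cell.M01	Activated_CD8_T_cell.M02	Activated_CD8_T_cell.M03	Activated_CD8_T_cell.M04	Activated_CD8_T_cell.M05	Activated_CD8_T_cell.M06	Activated_CD8_T_cell.M07	Activated_CD8_T_cell.M08	Activated_CD8_T_cell.M09	Activated_CD8_T_cell.M10
Activated_dendritic_cell	synthetic marker set	Activated_dendritic_cell.M01	Activated_dendritic_cell.M02	Activated_dendritic_cell.M03	Activated_dendritic_cell.M04	Activated_dendritic_cell.M05	Activated_dendritic_cell.M06	Activated_dendritic_cell.M07	Activated_dendritic_cell.M08	Activated_dendritic_cell.M09	Activated_dendritic_cell.M10
CD56bright_NK_cell	synthetic marker set	CD56bright_NK_cell.M01	CD56bright_NK_cell.M02	CD56bright_NK_cell.M03	CD56bright_NK_cell.M04	CD56bright_NK_cell.M05	CD56bright_NK_cell.M06	CD56bright_NK_cell.M07	CD56bright_NK_cell.M08	CD56bright_NK_cell.M09	CD56bright_NK_cell.M10
CD56dim_NK_cell	synthetic marker set	CD56dim_NK_cell.M01	CD56dim_NK_cell.M02	CD56dim_NK_cell.M03	CD56dim_NK_cell.M04	CD56dim_NK_cell.M05	CD56dim_NK_cell.M06	CD56dim_NK_cell.M07	CD56dim_NK_cell.M08	CD56dim_NK_cell.M09	CD56dim_NK_cell.M10
Central_memory_CD4_T_cell	synthetic marker set	Central_memory_CD4_T_cell.M01	Central_memory_CD4_T_cell.M02	Central_memory_CD4_T_cell.M03	Central_memory_CD4_T_cell.M04	Central_memory_CD4_T_cell.M05	Central_memory_CD4_T_cell.M06	Central_memory_CD4_T_cell.M07	Central_memory_CD4_T_cell.M08	Central_memory_CD4_T_cell.M09	Central_memory_CD4_T_cell.M10
Central_memory_CD8_T_cell	synthetic marker set	Central_memory_CD8_T_cell.M01	Central_memory_CD8_T_cell.M02	Central_memory_CD8_T_cell.M03	Central_memory_CD8_T_cell.M04	Central_memory_CD8_T_cell.M05	Central_memory_CD8_T_cell.M06	Central_memory_CD8_T_cell.M07	Central_memory_CD8_T_cell.M08	Central_memory_CD8_T_cell.M09	Central_memory_CD8_T_cell.M10
Effector_memory_CD4_T_cell	synthetic marker set	Effector_memory_CD4_T_cell.M01	Effector_memory_CD4_T_cell.M02	Effector_memory_CD4_T_cell.M03	Effector_memory_CD4_T_cell.M04	Effector_memory_CD4_T_cell.M05	Effector_memory_CD4_T_cell.M06	Effector_memory_CD4_T_cell.M07	Effector_memory_CD4_T_cell.M08	Effector_memory_CD4_T_cell.M09	Effector_memory_CD4_T_cell.M10
Effector_memory_CD8_T_cell	synthetic marker set	Effector_memory_CD8_T_cell.M01	Effector_memory_CD8_T_cell.M02	Effector_memory_CD8_T_cell.M03	Effector_memory_CD8_T_cell.M04	Effector_memory_CD8_T_cell.M05	Effector_memory_CD8_T_cell.M06	Effector_memory_CD8_T_cell.M07	Effector_memory_CD8_T_cell.M08	Effector_memory_CD8_T_cell.M09	Effector_memory_CD8_T_cell.M10
Eosinophil	synthetic marker set	Eosinophil.M01	Eosinophil.M02	Eosinophil.M03	Eosinophil.M04	Eosinophil.M05	Eosinophil.M06	Eosinophil.M07	Eosinophil.M08	Eosinophil.M09	Eosinophil.M10
Gamma_delta_T_cell	synthetic marker set	Gamma_delta_T_cell.M01	Gamma_delta_T_cell.M02	Gamma_delta_T_cell.M03	Gamma_delta_T_cell.M04	Gamma_delta_T_cell.M05	Gamma_delta_T_cell.M06	Gamma_delta_T_cell.M07	Gamma_delta_T_cell.M08	Gamma_delta_T_cell.M09	Gamma_delta_T_cell.M10
Immature_B_cell	synthetic marker set	Immature_B_cell.M01	Immature_B_cell.M02	Immature_B_cell.M03	Immature_B_cell.M04	Immature_B_cell.M05	Immature_B_cell.M06	Immature_B_cell.M07	Immature_B_cell.M08	Immature_B_cell.M09	Immature_B_cell.M10
Immature_dendritic_cell	synthetic marker set	Immature_dendritic_cell.M01	Immature_dendritic_cell.M02	Immature_dendritic_cell.M03	Immature_dendritic_cell.M04	Immature_dendritic_cell.M05	Immature_dendritic_cell.M06	Immature_dendritic_cell.M07	Immature_dendritic_cell.M08	Immature_dendritic_cell.M09	Immature_dendritic_cell.M10
MDSC	synthetic marker set	MDSC.M01	MDSC.M02	MDSC.M03	MDSC.M04	MDSC.M05	MDSC.M06	MDSC.M07	MDSC.M08	MDSC.M09	MDSC.M10
Macrophage	synthetic marker set	Macrophage.M01	Macrophage.M02	Macrophage.M03	Macrophage.M04	Macrophage.M05	Macrophage.M06	Macrophage.M07	Macrophage.M08	Macrophage.M09	Macrophage.M10
Mast_cell	synthetic marker set	Mast_cell.M01	Mast_cell.M02	Mast_cell.M03	Mast_cell.M04	Mast_cell.M05	Mast_cell.M06	Mast_cell.M07	Mast_cell.M08	Mast_cell.M09	Mast_cell.M10
Memory_B_cell	synthetic marker set	Memory_B_cell.M01	Memory_B_cell.M02	Memory_B_cell.M03	Memory_B_cell.M04	Memory_B_cell.M05	Memory_B_cell.M06	Memory_B_cell.M07	Memory_B_cell.M08	Memory_B_cell.M09	Memory_B_cell.M10
Monocyte	synthetic marker set	Monocyte.M01	Monocyte.M02	Monocyte.M03	Monocyte.M04	Monocyte.M05	Monocyte.M06	Monocyte.M07	Monocyte.M08	Monocyte.M09	Monocyte.M10
NK_T_cell	synthetic marker set	NK_T_cell.M01	NK_T_cell.M02	NK_T_cell.M03	NK_T_cell.M04	NK_T_cell.M05	NK_T_cell.M06	NK_T_cell.M07	NK_T_cell.M08	NK_T_cell.M09	NK_T_cell.M10
NK_cell	synthetic marker set	NK_cell.M01	NK_cell.M02	NK_cell.M03	NK_cell.M04	NK_cell.M05	NK_cell.M06	NK_cell.M07	NK_cell.M08	NK_cell.M09	NK_cell.M10
Neutrophil	synthetic marker set	Neutrophil.M01	Neutrophil.M02	Neutrophil.M03	Neutrophil.M04	Neutrophil.M05	Neutrophil.M06	Neutrophil.M07	Neutrophil.M08	Neutrophil.M09	Neutrophil.M10
Plasmacytoid_dendritic_cell	synthetic marker set	Plasmacytoid_dendritic_cell.M01	Plasmacytoid_dendritic_cell.M02	Plasmacytoid_dendritic_cell.M03	Plasmacytoid_dendritic_cell.M04	Plasmacytoid_dendritic_cell.M05	Plasmacytoid_dendritic_cell.M06	Plasmacytoid_dendritic_cell.M07	Plasmacytoid_dendritic_cell.M08	Plasmacytoid_dendritic_cell.M09	Plasmacytoid_dendritic_cell.M10
Regulatory_T_cell	synthetic marker set	Regulatory_T_cell.M01	Regulatory_T_cell.M02	Regulatory_T_cell.M03	Regulatory_T_cell.M04	Regulatory_T_cell.M05	Regulatory_T_cell.M06	Regulatory_T_cell.M07	Regulatory_T_cell.M08	Regulatory_T_cell.M09	Regulatory_T_cell.M10
T_follicular_helper_cell	synthetic marker set	T_follicular_helper_cell.M01	T_follicular_helper_cell.M02	T_follicular_helper_cell.M03	T_follicular_helper_cell.M04	T_follicular_helper_cell.M05	T_follicular_helper_cell.M06	T_follicular_helper_cell.M07	T_follicular_helper_cell.M08	T_follicular_helper_cell.M09	T_follicular_helper_cell.M10
Type_1_T_helper_cell	synthetic marker set	Type_1_T_helper_cell.M01	Type_1_T_helper_cell.M02	Type_1_T_helper_cell.M03	Type_1_T_helper_cell.M04	Type_1_T_helper_cell.M05	Type_1_T_helper_cell.M06	Type_1_T_helper_cell.M07	Type_1_T_helper_cell.M08	Type_1_T_helper_cell.M09	Type_1_T_helper_cell.M10
Type_17_T_helper_cell	synthetic marker set	Type_17_T_helper_cell.M01	Type_17_T_helper_cell.M02	Type_17_T_helper_cell.M03	Type_17_T_helper_cell.M04	Type_17_T_helper_cell.M05	Type_17_T_helper_cell.M06	Type_17_T_helper_cell.M07	Type_17_T_helper_cell.M08	Type_17_T_helper_cell.M09	Type_17_T_helper_cell.M10
Type_2_T_helper_cell	synthetic marker set	Type_2_T_helper_cell.M01	Type_2_T_helper_cell.M02	Type_2_T_helper_cell.M03	Type_2_T_helper_cell.M04	Type_2_T_helper_cell.M05	Type_2_T_helper_cell.M06	Type_2_T_helper_cell.M07	Type_2_T_helper_cell.M08	Type_2_T_helper_cell.M09	Type_2_T_helper_cell.M10
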