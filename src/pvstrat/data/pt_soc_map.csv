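pt_code,pt_name,soc_code,soc_name
immune_system_disorder,Immune system disorder,SOC_IMM,Immune system disorders
acne,Acne,SOC_SKIN,Skin and subcutaneous tissue disorders
erythema_nodosum,Erythema nodosum,SOC_SKIN,Skin and subcutaneous tissue disorders
vitiligo,Vitiligo,SOC_SKIN,Skin and subcutaneous tissue disorders
psoriasis,Psoriasis,SOC_SKIN,Skin and subcutaneous tissue disorders
seronegative_arthritis,Seronegative arthritis,SOC_MSK,Musculoskeletal and connective tissue disorders
hypereosinophilic_syndrome,Hypereosinophilic syndrome,SOC_BLOOD,Blood and lymphatic system disorders
knee_operation,Knee operation,SOC_SURG,Surgical and medical procedures
cutaneous_t_cell_lymphoma_stage_i,Cutaneous T-cell lymphoma stage I,SOC_NEO,Neoplasms benign malignant and unspecified
cutaneous_t_cell_lymphoma_stage_ii,Cutaneous T-cell lymphoma stage II,SOC_NEO,Neoplasms benign malignant and unspecified
cutaneous_t_cell_lymphoma_stage_iii,Cutaneous T-cell lymphoma stage III,SOC_NEO,Neoplasms benign malignant and unspecified
cutaneous_t_cell_lymphoma_stage_iv,Cutaneous T-cell lymphoma stage IV,SOC_NEO,Neoplasms benign malignant and unspecified
seminoma,Seminoma,SOC_NEO,Neoplasms benign malignant and unspecified
atopic_keratoconjunctivitis,Atopic keratoconjunctivitis,SOC_EYE,Eye disorders
blepharitis,Blepharitis,SOC_EYE,Eye disorders
conjunctivitis,Conjunctivitis,SOC_EYE,Eye disorders
corneal_erosion,Corneal erosion,SOC_EYE,Eye disorders
dry_eye,Dry eye,SOC_EYE,Eye disorders
episcleritis,Episcleritis,SOC_EYE,Eye disorders
cataract,Cataract,SOC_EYE,Eye disorders
keratoconus,Keratoconus,SOC_EYE,Eye disorders
acanthosis_nigricans,Acanthosis nigricans,SOC_SKIN,Skin and subcutaneous tissue disorders
acarodermatitis,Acarodermatitis,SOC_INF,Infections and infestations
alopecia,Alopecia,SOC_SKIN,Skin and subcutaneous tissue disorders
alopecia_totalis,Alopecia totalis,SOC_SKIN,Skin and subcutaneous tissue disorders
alopecia_areata,Alopecia areata,SOC_SKIN,Skin and subcutaneous tissue disorders
dry_skin,Dry skin,SOC_SKIN,Skin and subcutaneous tissue disorders
erysipelas,Erysipelas,SOC_INF,Infections and infestations
eye_infection,Eye infection,SOC_INF,Infections and infestations
staphylococcal_infection,Staphylococcal infection,SOC_INF,Infections and infestations
streptococcal_pharyngitis,Streptococcal pharyngitis,SOC_INF,Infections and infestations
arthralgia,Arthralgia,SOC_MSK,Musculoskeletal and connective tissue disorders
back_disorder,Back disorder,SOC_MSK,Musculoskeletal and connective tissue disorders
peak_expiratory_flow_rate_decreased,Peak expiratory flow rate decreased,SOC_INV,Investigations
pulmonary_congestion,Pulmonary congestion,SOC_RESP,Respiratory thoracic and mediastinal disorders
hyposmia,Hyposmia,SOC_NERV,Nervous system disorders
headache,Headache,SOC_NERV,Nervous system disorders
nasopharyngitis,Nasopharyngitis,SOC_INF,Infections and infestations
injection_site_reaction,Injection site reaction,SOC_GEN,General disorders and administration site conditions
nausea,Nausea,SOC_GI,Gastrointestinal disorders
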