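{
  "nsclc_collection": {
    "table": {"NSCLC": 5676, "LUAS": 120, "LUAD": 3295, "LUSC": 893, "other_subtypes": 1488},
    "provenance": "Surgical NSCLC collection, Fudan University Shanghai Cancer Center, 2007-2017; LUAS defined as >=10% adenomatous and squamous pathology in a single tumor",
    "derived_count": false
  },
  "cohort_stage": {
    "table": {"total": 109, "stage_I": 55, "stage_II": 19, "stage_III": 34, "stage_IV": 1},
    "provenance": "Chinese LUAS sequencing cohort (n=109), TNM stage distribution",
    "derived_count": false
  },
  "smoking": {
    "table": {"total": 109, "non_smoker": 51, "smoker": 58},
    "provenance": "Chinese LUAS sequencing cohort (n=109); non-smoker count back-computed from the reported 46.8% proportion",
    "derived_count": true
  },
  "gender": {
    "table": {"total": 109, "male": 71, "female": 38},
    "provenance": "Chinese LUAS sequencing cohort (n=109), sex distribution",
    "derived_count": false
  },
  "egfr_alleles": {
    "table": {"EGFR_mutant": 40, "L858R": 20, "ex19del": 10},
    "provenance": "EGFR hot-spot alleles among EGFR-mutant LUAS tumors",
    "derived_count": false
  },
  "erbb2_alleles": {
    "table": {"ERBB2_mutant": 7, "ex20ins": 4},
    "provenance": "ERBB2 hot-spot alleles among ERBB2-mutant LUAS tumors; exon 20 insertions dominant",
    "derived_count": false
  },
  "alk_fusion": {
    "table": {"rnaseq_samples": 93, "ALK_fusion": 7, "EML4_ALK": 6, "KIF5B_ALK": 1},
    "provenance": "In-frame ALK fusions called from RNA-seq of 93 LUAS tumors",
    "derived_count": false
  },
  "alk_in_C1": {
    "table": {"ALK_fusion": 6, "in_C1": 5},
    "provenance": "ALK fusions falling in DNA-class C1 of the genomic clustering (5 of 6, 83.3%)",
    "derived_count": false
  },
  "eml4_alk_mouse": {
    "table": {"mice": 8, "AST_positive": 6},
    "provenance": "Trp53-null mice carrying lentiviral EML4-ALK(L1196M); AST-positive count back-computed from the reported 75% penetrance",
    "derived_count": true
  }
}
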