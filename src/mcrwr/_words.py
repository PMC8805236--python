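"""Fixed filler vocabulary for synthetic titles and abstracts.

A mix of general scientific prose words; shared across all synthetic
documents so the stem-based baseline sees realistic shared-token noise.
"""

FILLER_WORDS = [
    "analysis", "approach", "assay", "association", "between", "binding",
    "biological", "cell", "cells", "changes", "clinical", "cohort",
    "combined", "compared", "comparison", "complex", "conditions", "control",
    "controls", "correlated", "culture", "data", "decrease", "decreased",
    "detected", "determine", "development", "different", "differential",
    "distinct", "distribution", "effect", "effects", "elevated", "evidence",
    "examined", "experimental", "experiments", "expression", "factor",
    "factors", "findings", "followed", "following", "function", "functional",
    "further", "growth", "higher", "human", "identified", "important",
    "increase", "increased", "indicate", "indicated", "induced", "influence",
    "interaction", "investigated", "involved", "level", "levels", "lower",
    "measured", "mechanism", "mechanisms", "mediated", "method", "methods",
    "model", "models", "molecular", "multiple", "normal", "observed",
    "obtained", "pathway", "pathways", "patients", "pattern", "performed",
    "population", "potential", "presence", "present", "previous", "primary",
    "process", "processes", "production", "profile", "protein", "proteins",
    "range", "rates", "reduced", "region", "regions", "regulation",
    "related", "relative", "reported", "response", "responses", "results",
    "revealed", "role", "sample", "samples", "selected", "sequence",
    "several", "significant", "significantly", "similar", "specific",
    "structure", "studied", "studies", "study", "suggest", "suggested",
    "system", "systems", "target", "tested", "tissue", "tissues",
    "treatment", "type", "types", "values", "variation", "whereas", "within",
]

CONCEPT_WORDS = [
    "apoptosis", "angiogenesis", "biomarker", "carcinoma", "chemokine",
    "chromatin", "cytokine", "dystrophy", "enzyme", "epithelium", "fibrosis",
    "genome", "glycoprotein", "hormone", "hypoxia", "inflammation", "kinase",
    "ligand", "lymphocyte", "macrophage", "membrane", "metabolism",
    "methylation", "microbiome", "mitochondria", "mutation", "necrosis",
    "neuron", "oncogene", "pathogen", "peptide", "phenotype", "plasma",
    "polymorphism", "promoter", "receptor", "regeneration", "ribosome",
    "sclerosis", "secretion", "signaling", "stenosis", "substrate",
    "synapse", "telomere", "thrombosis", "transcription", "translocation",
    "tumor", "vaccine", "vesicle",
]
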