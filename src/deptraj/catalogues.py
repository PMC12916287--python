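"""Synthetic analyte catalogues for the biomarker panels.

These catalogues are synthetic stand-ins that emulate the structure of the
assay panels used in this line of work: a 92-protein inflammation panel
(Olink-style, NPX log2 scale) and an NMR metabolomics feature set from
which lipoprotein subclass measures are excluded, leaving 57 features in
nine categories (9 cholesterol, 12 apolipoproteins/lipids, 3 particle
sizes, 16 fatty acids, 3 glycolysis, 8 amino acids, 3 ketone bodies,
2 fluid balance, 1 inflammation).  Names follow field conventions but the
panel membership itself carries no information used by any computation;
only counts, families and categories matter downstream.
"""

from __future__ import annotations

import pandas as pd

# 92 inflammation-panel proteins (synthetic emulation of an Olink-style panel)
INFLAMMATION_PROTEINS: tuple[str, ...] = (
    "IL6", "IL8", "IL10", "IL18", "IL7", "IL15", "IL17A", "IL17C", "IL20",
    "IL24", "IL33", "IL2RB", "IL10RA", "IL10RB", "IL12B", "IL18R1", "IL22RA1",
    "TNF", "TNFB", "TNFSF14", "TRAIL", "TWEAK", "TRANCE", "OPG", "CD40",
    "CD5", "CD6", "CD8A", "CD244", "CD274", "CDCP1", "CCL2", "CCL3", "CCL4",
    "CCL8", "CCL11", "CCL13", "CCL19", "CCL20", "CCL23", "CCL25", "CCL28",
    "CXCL1", "CXCL5", "CXCL6", "CXCL9", "CXCL10", "CXCL11", "CX3CL1",
    "FGF5", "FGF19", "FGF21", "FGF23", "HGF", "VEGFA", "LAPTGFB1", "TGFA",
    "BDNF", "BNGF", "NT3", "GDNF", "NRTN", "ARTN", "CSF1", "FLT3L", "SCF",
    "MMP1", "MMP10", "UPA", "TSLP", "SLAMF1", "SIRT2", "STAMBP", "SULT1A1",
    "AXIN1", "CASP8", "4EBP1", "ADA", "CST5", "DNER", "ENRAGE", "GAL9",
    "LIFR", "MCP3", "MCP4", "OSM", "PDL1", "IFNG", "EIF4G1", "TNFRSF9",
    "NTPDase8", "ITGB6",
)

assert len(INFLAMMATION_PROTEINS) == 92

# 57 retained NMR metabolomic features by category, plus excluded subclasses
_METABOLOMIC_FEATURES: dict[str, tuple[str, ...]] = {
    "cholesterol": (
        "Total_C", "non_HDL_C", "Remnant_C", "VLDL_C", "Clinical_LDL_C",
        "LDL_C", "HDL_C", "HDL2_C", "HDL3_C",
    ),
    "apolipoproteins_lipids": (
        "ApoA1", "ApoB", "ApoB_by_ApoA1", "Total_TG", "VLDL_TG", "LDL_TG",
        "HDL_TG", "Total_PL", "Total_CE", "Total_FC", "Total_L", "TG_by_PG",
    ),
    "particle_size": ("VLDL_size", "LDL_size", "HDL_size"),
    "fatty_acids": (
        "Total_FA", "Unsaturation", "Omega_3", "Omega_6", "PUFA", "MUFA",
        "SFA", "LA", "DHA", "Omega_3_pct", "Omega_6_pct", "PUFA_pct",
        "MUFA_pct", "SFA_pct", "LA_pct", "DHA_pct",
    ),
    "glycolysis": ("Glucose", "Lactate", "Citrate"),
    "amino_acids": (
        "Alanine", "Glutamine", "Glycine", "Histidine", "Isoleucine",
        "Leucine", "Valine", "Phenylalanine",
    ),
    "ketone_bodies": ("Acetate", "Acetoacetate", "bOHbutyrate"),
    "fluid_balance": ("Albumin", "Creatinine"),
    "inflammation": ("GlycA",),
}

# a representative block of lipoprotein subclass measures (excluded downstream)
_LIPOPROTEIN_SUBCLASSES: tuple[str, ...] = tuple(
    f"{cls}_{comp}"
    for cls in ("XXL_VLDL", "XL_VLDL", "L_VLDL", "M_VLDL", "S_VLDL", "XS_VLDL",
                "IDL", "L_LDL", "M_LDL", "S_LDL", "XL_HDL", "L_HDL", "M_HDL",
                "S_HDL")
    for comp in ("P", "L", "C")
)


def protein_catalogue() -> pd.DataFrame:
    """Metadata table for the 92-analyte inflammation protein panel."""
    return pd.DataFrame(
        {
            "analyte": list(INFLAMMATION_PROTEINS),
            "family": "protein",
            "category": "inflammation_protein",
        }
    )


def metabolomic_catalogue(include_subclasses: bool = False) -> pd.DataFrame:
    """Metadata for the NMR metabolomics feature set.

    With ``include_subclasses=True`` the redundant lipoprotein-subclass
    block is appended (category ``lipoprotein_subclass``); the retained
    set has exactly 57 features in the stated category composition.
    """
    rows = [
        {"analyte": name, "family": "metabolomic", "category": cat}
        for cat, names in _METABOLOMIC_FEATURES.items()
        for name in names
    ]
    if include_subclasses:
        rows += [
            {"analyte": name, "family": "metabolomic", "category": "lipoprotein_subclass"}
            for name in _LIPOPROTEIN_SUBCLASSES
        ]
    return pd.DataFrame(rows)


BLOOD_COUNT_CHEMISTRY: tuple[str, ...] = (
    "WBC", "RBC", "Hb", "Hct", "MCV", "MCH", "MCHC", "Platelets",
    "Neutrophils", "Lymphocytes", "Monocytes", "Eosinophils", "Basophils",
    "CRP", "Glucose_serum", "Insulin", "HOMA_IR", "HDL_chol", "LDL_chol",
    "VLDL_chol", "Total_chol", "Triglycerides", "ALT", "AST", "GGT",
    "P3NP", "AST_ALT_ratio", "Urea",
)


def blood_count_catalogue() -> pd.DataFrame:
    """Metadata for the blood count / clinical chemistry measures."""
    return pd.DataFrame(
        {
            "analyte": list(BLOOD_COUNT_CHEMISTRY),
            "family": "blood_count_chemistry",
            "category": "blood_count_chemistry",
        }
    )
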