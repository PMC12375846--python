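"""Shipped default configuration: test characteristics, costs, utilities
and treatment-assignment rules.

Only a handful of these numbers are fixed by published German sources (the
PSA test at 25.61 2023-euros, the 500-euro base-case MRI and its 120-euro
scenario price, the 75/95/65% participation rates).  Everything else is a
documented placeholder in the range reported by the screening-trial and
cost-effectiveness literature, and every value is overridable through the
configuration layer.
"""

from __future__ import annotations

from .screening import TestProfile


def default_test_profiles() -> dict:
    """Test characteristics keyed by test name.

    DRE sensitivity rises with local extent (palpability); MRI separates
    clinically significant (GS >= 7) from insignificant disease, which is
    what lets MRI triage cut benign biopsies and overdiagnosis; biopsies
    have specificity 1 (a biopsy of a man without cancer is negative).
    """
    return {
        "dre": TestProfile(
            test_name="dre",
            sensitivity={"by_tcat": [0.18, 0.40, 0.60], "met": 0.80},
            specificity=0.94,
        ),
        "mri": TestProfile(
            test_name="mri",
            sensitivity={"by_grade": [0.55, 0.93, 0.95]},
            specificity=0.70,
        ),
        "systematic_biopsy": TestProfile(
            test_name="systematic_biopsy",
            sensitivity={"by_grade": [0.70, 0.82, 0.90]},
            specificity=1.0,
        ),
        "combined_biopsy": TestProfile(
            test_name="combined_biopsy",
            sensitivity={"by_grade": [0.75, 0.92, 0.96]},
            specificity=1.0,
        ),
    }


def default_costs() -> dict:
    """Per-event and per-year costs in 2023 euros."""
    return {
        "psa_test": 25.61,
        "dre_test": 25.0,
        "mri": 500.0,
        "systematic_biopsy": 360.0,
        "combined_biopsy": 740.0,
        "as_visit": 48.0,  # PSA + DRE monitoring visit
        "as_mri_biopsy": 1240.0,  # periodic MRI + combined biopsy
        "clinical_workup_mri": 1240.0,  # symptomatic work-up, MRI pathway
        "clinical_workup_sbx": 360.0,  # symptomatic work-up, SBx pathway
        "radical_treatment": 13000.0,  # prostatectomy / radiotherapy average
        "followup_visit_per_year": 95.0,
        "followup_years": 10.0,
        "adt_chemo_per_year": 8000.0,
        "palliative_per_year": 15000.0,
        "invitation": 0.0,
    }


def default_utilities(utility_set: str = "PORPUS-U") -> dict:
    """Health-state utilities, phase durations (years) and the age-specific
    background utility curve (multiplicative model).

    The PORPUS-U set runs higher than EQ-5D for the same states; swapping
    sets changes QALYs only.
    """
    if utility_set == "PORPUS-U":
        state = {
            "screen_attendance": (0.99, 0.02),
            "biopsy": (0.92, 0.06),
            "diagnosis": (0.85, 0.20),
            "radical_treatment": (0.80, 0.50),
            "post_treatment": (0.95, 9.5),
            "active_surveillance": (0.97, None),  # until switch/death
            "adt_chemo": (0.80, None),
            "palliative_terminal": (0.40, 0.5),
        }
    elif utility_set == "EQ-5D":
        state = {
            "screen_attendance": (0.99, 0.02),
            "biopsy": (0.90, 0.06),
            "diagnosis": (0.80, 0.20),
            "radical_treatment": (0.72, 0.50),
            "post_treatment": (0.93, 9.5),
            "active_surveillance": (0.95, None),
            "adt_chemo": (0.72, None),
            "palliative_terminal": (0.32, 0.5),
        }
    else:
        raise ValueError(f"unknown utility set '{utility_set}'")
    return {
        "utility_set_name": utility_set,
        "background_ages": [35.0, 45.0, 55.0, 65.0, 75.0, 85.0, 105.0],
        "background_values": [0.94, 0.92, 0.90, 0.86, 0.80, 0.74, 0.62],
        "state_utility": {k: v[0] for k, v in state.items()},
        "state_duration_years": {k: v[1] for k, v in state.items()},
    }


def default_treatment_rules() -> dict:
    """Treatment modality by grade / stage / age at diagnosis.

    Localized GS<7 below the age cutoff goes to active surveillance;
    other localized disease below the radical cutoff receives radical
    treatment; metastatic (or very late-age) disease is managed with
    ADT/chemotherapy.
    """
    return {"as_grade_max": 0, "as_age_max": 70.0, "radical_age_max": 75.0}


def default_economic_config() -> dict:
    return {
        "discount_rate": 0.03,
        "discount_reference_age": 45.0,
        "costs": default_costs(),
        "utilities": default_utilities("PORPUS-U"),
        "treatment_rules": default_treatment_rules(),
        # palliative pathway before cancer death
        "adt_years_before_death": 2.0,
        "terminal_years": 0.5,
    }
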