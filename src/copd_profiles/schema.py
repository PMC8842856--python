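"""Column dictionary for cohort tables.

All tabular artifacts are comma-separated UTF-8 text with a header row and one
participant-timepoint per row. Unknown columns pass through untouched.
"""

from __future__ import annotations

#: The 13 variables entering standardization, PCA and clustering.
CLUSTERING_VARIABLES: list[str] = [
    "age",         # years
    "bmi",         # kg/m^2
    "pack_years",  # cumulative cigarette exposure
    "cci",         # Charlson Comorbidity Index, integer score
    "fev1_pct",    # FEV1, % of predicted
    "fvc_pct",     # FVC, % of predicted
    "cat",         # COPD Assessment Test, 0-40, integer
    "mmrc",        # modified MRC dyspnoea scale, 0-4, integer
    "hads_a",      # HADS anxiety subscale, 0-21, integer
    "hads_d",      # HADS depression subscale, 0-21, integer
    "sgrq_total",  # St George's Respiratory Questionnaire total, 0-100
    "qms_pct",     # quadriceps muscle strength, % of predicted
    "sts_pct",     # 1-minute sit-to-stand repetitions, % of predicted
]

#: Clinical descriptors carried alongside the clustering variables.
DESCRIPTOR_COLUMNS: list[str] = [
    "exacerbations",    # acute exacerbations in the previous year, count
    "hospitalisations", # respiratory hospitalisations in the previous year, count
    "sex",              # 'male' / 'female'
    "smoking_status",   # 'current' / 'former' / 'never'
    "bpaat",            # brief physical activity assessment tool, 0-8, integer
]

#: Full cohort table layout. ``latent_profile`` is generator-only ground truth
#: (1-4) and is absent from real data.
COHORT_COLUMNS: list[str] = (
    ["participant_id", "timepoint"]
    + CLUSTERING_VARIABLES
    + DESCRIPTOR_COLUMNS
    + ["latent_profile"]
)

#: Instrument-range bounds used for validation and for truncating sampling
#: distributions. Open-ended scales carry plausibility bounds.
VARIABLE_BOUNDS: dict[str, tuple[float, float]] = {
    "age": (35.0, 95.0),
    "bmi": (13.0, 45.0),
    "pack_years": (0.0, 200.0),
    "cci": (0.0, 20.0),
    "fev1_pct": (10.0, 130.0),
    "fvc_pct": (20.0, 150.0),
    "cat": (0.0, 40.0),
    "mmrc": (0.0, 4.0),
    "hads_a": (0.0, 21.0),
    "hads_d": (0.0, 21.0),
    "sgrq_total": (0.0, 100.0),
    "qms_pct": (10.0, 180.0),
    "sts_pct": (10.0, 180.0),
    "bpaat": (0.0, 8.0),
}

#: Variables reported on integer scales (rounded half-up after sampling).
INTEGER_VARIABLES: frozenset[str] = frozenset(
    {"cci", "cat", "mmrc", "hads_a", "hads_d", "bpaat"}
)

#: Variables re-measured at every monthly follow-up visit; everything else is
#: carried forward from baseline within the 6-month window.
TIME_VARYING_VARIABLES: list[str] = ["fev1_pct", "cat", "mmrc", "qms_pct", "sts_pct"]
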