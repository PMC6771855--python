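"""Shared vocabulary for the trial dataset.

Every module in the package speaks the same schema: resource-use
categories, PlGF bands, final-diagnosis strata, trial arms and delivery
modes, with the literal tokens used in the delimited-text interchange
files.
"""

from __future__ import annotations

# Resource-use categories. Outpatient is a visit count; everything else is
# a length of stay in days. Infant ICU/HDU additionally carries an
# admission flag (days > 0 iff admitted).
MATERNAL_CATEGORIES: tuple[str, ...] = (
    "outpatient",
    "antenatal_ward",
    "labour_ward",
    "maternal_postnatal",
    "maternal_icu_hdu",
)
INFANT_CATEGORIES: tuple[str, ...] = ("infant_icu_hdu", "infant_scbu")
CATEGORIES: tuple[str, ...] = MATERNAL_CATEGORIES + INFANT_CATEGORIES

CATEGORY_UNITS: dict[str, str] = {
    "outpatient": "attendance",
    "antenatal_ward": "bed_day",
    "labour_ward": "bed_day",
    "maternal_postnatal": "bed_day",
    "maternal_icu_hdu": "bed_day",
    "infant_icu_hdu": "bed_day",
    "infant_scbu": "bed_day",
}

# PlGF concentration bands (pg/ml): normal, low, very low.
PLGF_BANDS: tuple[str, ...] = ("gt100", "12to100", "lt12")

# Final diagnosis strata: none of the below; gestational hypertension /
# chronic hypertension / small-for-gestational-age; pre-eclampsia.
DIAGNOSES: tuple[str, ...] = ("normal", "GH_CHT_SGA", "preeclampsia")

# The nine analysis subgroups, in reporting order (PlGF band major,
# diagnosis minor) matching the published table layout.
SUBGROUPS: tuple[tuple[str, str], ...] = tuple(
    (band, dx) for band in PLGF_BANDS for dx in DIAGNOSES
)

ARMS: tuple[str, str] = ("usual", "revealed")

DELIVERY_MODES: tuple[str, ...] = (
    "spontaneous",
    "assisted",
    "planned_CS",
    "emergency_CS",
)

#: columns of the one-row-per-woman records file, in order
RECORD_COLUMNS: tuple[str, ...] = (
    "id",
    "cluster",
    "step",
    "arm",
    "plgf_category",
    "diagnosis",
    *CATEGORIES,
    "infant_icu_hdu_admitted",
    "delivery_mode",
    "adverse_event",
)


def subgroup_label(plgf_category: str, diagnosis: str) -> str:
    """Canonical single-token label for one of the 9 subgroup cells."""
    return f"{plgf_category}:{diagnosis}"


SUBGROUP_LABELS: tuple[str, ...] = tuple(subgroup_label(b, d) for b, d in SUBGROUPS)
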