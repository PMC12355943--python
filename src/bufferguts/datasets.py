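"""Bundled summary of honeybee standard regulatory toxicity tests.

Endpoint table for five plant-protection compounds tested on *Apis
mellifera* under the standard acute contact (AC), acute oral (AO) and
chronic oral (CO) designs.  Acute endpoints are 48-h LD50s in ug a.i./bee;
the food-concentration column carries the 48-h LC50 for acute-oral tests
(derived at 20 mg food consumed per bee) and the 10-day LC50 for chronic
tests, both in mg a.i./kg food.  The table serves as the worked-example
input for the unit-conversion and outlier-exclusion routines.
"""

from __future__ import annotations

import pandas as pd

_DESIGN = {"AC": "acute_contact", "AO": "acute_oral", "CO": "chronic_oral"}

# compound, report_no, design, ld50_48h_ug_bee, ld50_10d_ug_bee_day, lc50_mg_kg
_TESTS = [
    ("Deltamethrin", "M-149494", "AC", 0.262, None, None),
    ("Deltamethrin", "M-444971", "AC", 0.119, None, None),
    ("Deltamethrin", "M-149496", "AO", 1.45, None, 72.4),
    ("Deltamethrin", "M-444971", "AO", 0.164, None, 8.21),
    ("Deltamethrin", "M-477250", "CO", None, 0.648, 18.0),
    ("Ethiprole", "M-192387", "AC", 0.0127, None, None),
    ("Ethiprole", "M-214951", "AC", 0.0540, None, None),
    ("Ethiprole", "M-192387", "AO", 0.0336, None, 1.68),
    ("Ethiprole", "M-214951", "AO", 0.0327, None, 1.64),
    ("Ethiprole", "M-581904", "CO", None, 0.000695, 0.0478),
    ("Imidacloprid", "M-006940", "AC", 0.0819, None, None),
    ("Imidacloprid", "M-067751", "AC", 0.0445, None, None),
    ("Imidacloprid", "M-068023", "AC", 0.0728, None, None),
    ("Imidacloprid", "M-006940", "AO", 0.00348, None, 0.174),
    ("Imidacloprid", "M-016942", "AO", 0.0763, None, 3.81),
    ("Imidacloprid", "M-067751", "AO", 0.0945, None, 4.73),
    ("Imidacloprid", "M-067996", "AO", 0.136, None, 6.80),
    ("Imidacloprid", "M-068023", "AO", 0.102, None, 5.08),
    ("Imidacloprid", "M-600686", "CO", None, 0.128, 1.32),
    ("Tetraniliprole", "M-438810", "AC", 0.993, None, None),
    ("Tetraniliprole", "M-441758", "AC", 1.34, None, None),
    ("Tetraniliprole", "M-438810", "AO", 0.106, None, 5.28),
    ("Tetraniliprole", "M-441758", "AO", 0.0107, None, 0.537),
    ("Tetraniliprole", "M-551955", "CO", None, 0.0173, 0.710),
    ("Thiacloprid", "M-000856", "AC", 40.7, None, None),
    ("Thiacloprid", "M-001004", "AC", 44.2, None, None),
    ("Thiacloprid", "M-000856", "AO", 17.5, None, 873.0),
    ("Thiacloprid", "M-001004", "AO", 13.7, None, 684.0),
    ("Thiacloprid", "M-475374", "CO", None, 2.99, 48.9),
]


def honeybee_regulatory_tests() -> pd.DataFrame:
    """Endpoint table of the bundled honeybee regulatory tests.

    Columns: ``compound, report_no, design, ld50_48h_ug_bee,
    ld50_10d_ug_bee_day, lc50_48h_or_10d_mg_kg``.
    """
    df = pd.DataFrame(
        _TESTS,
        columns=[
            "compound",
            "report_no",
            "design",
            "ld50_48h_ug_bee",
            "ld50_10d_ug_bee_day",
            "lc50_48h_or_10d_mg_kg",
        ],
    )
    df["design"] = df["design"].map(_DESIGN)
    return df
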