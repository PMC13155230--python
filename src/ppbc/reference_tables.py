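"""Published characteristics of the 336-woman parous reference cohort.

The study that motivates this package printed its cohort-description table in
full: per-subtype counts of every demographic and reproductive characteristic
for 336 parous young-onset breast cancer patients. Those counts are
transcribed here verbatim as labeled contingency tables so that the
descriptive test machinery (:mod:`ppbc.cohort_stats`) can be validated against
printed statistics without access to the individual-level data (available
only upon request to the study authors).

Each table records which rows and columns represent "Missing" so callers can
choose whether to include them in tests; the printed p-values were computed
with the missing-subtype column excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ReferenceTable", "reference_cohort_tables", "CONTINUOUS_SUMMARIES"]

#: Subtype columns in printed order; "missing" is the unknown-subtype column.
SUBTYPE_COLUMNS = ("missing", "luminal A", "luminal B", "HER2", "TNBC")


@dataclass
class ReferenceTable:
    """One characteristic's per-subtype counts plus missing-level bookkeeping."""

    name: str
    counts: pd.DataFrame  # rows = levels, columns = SUBTYPE_COLUMNS
    overall: pd.Series  # printed overall column (n = 336)
    printed_p: float | None = None
    missing_rows: list[str] = field(default_factory=list)
    missing_cols: list[str] = field(default_factory=lambda: ["missing"])

    def test_table(self, include_missing: bool = False) -> pd.DataFrame:
        """Counts ready for a test: missing rows/columns dropped by default."""
        t = self.counts
        if not include_missing:
            t = t.drop(index=self.missing_rows, columns=self.missing_cols)
        return t


def _table(name, levels, rows, printed_p, missing_rows=()):
    counts = pd.DataFrame(
        np.array([r[1:] for r in rows]), index=levels, columns=list(SUBTYPE_COLUMNS)
    )
    overall = pd.Series([r[0] for r in rows], index=levels, name="overall")
    return ReferenceTable(
        name=name,
        counts=counts,
        overall=overall,
        printed_p=printed_p,
        missing_rows=list(missing_rows),
    )


def reference_cohort_tables() -> dict[str, ReferenceTable]:
    """All printed contingency tables, keyed by variable name.

    Row tuples are ``(overall, missing-subtype, luminal A, luminal B, HER2,
    TNBC)`` exactly as printed.
    """
    tables = [
        _table(
            "age_menarche",
            ["<12", "12-13", "14+", "Missing"],
            [(45, 3, 10, 15, 5, 12), (127, 14, 43, 53, 7, 10),
             (55, 3, 16, 27, 7, 2), (109, 1, 35, 53, 7, 13)],
            0.01, missing_rows=["Missing"],
        ),
        _table(
            "n_pregnancies",
            ["0", "1", "2", "3-5", "Missing"],
            [(1, 0, 0, 1, 0, 0), (53, 3, 14, 25, 2, 9), (128, 8, 47, 51, 11, 11),
             (141, 10, 40, 63, 11, 17), (13, 0, 3, 8, 2, 0)],
            0.55, missing_rows=["Missing"],
        ),
        _table(
            "n_children",
            ["0", "1", "2", "3+", "Missing"],
            [(1, 0, 1, 0, 0, 0), (92, 5, 26, 43, 4, 14), (161, 10, 51, 70, 14, 16),
             (68, 5, 23, 26, 7, 7), (14, 1, 3, 9, 1, 0)],
            0.6, missing_rows=["Missing"],
        ),
        _table(
            "miscarriages",
            ["0", "1", "2+", "Missing"],
            [(227, 14, 76, 98, 16, 23), (68, 5, 13, 36, 5, 9),
             (26, 1, 12, 5, 3, 5), (15, 1, 3, 9, 2, 0)],
            0.05, missing_rows=["Missing"],
        ),
        _table(
            "stillbirths",
            ["0", "1", "Missing"],
            [(317, 20, 100, 136, 25, 36), (5, 0, 1, 3, 0, 1), (14, 1, 3, 9, 1, 0)],
            0.6, missing_rows=["Missing"],
        ),
        _table(
            "abortions",
            ["0", "1+", "Missing"],
            [(263, 17, 83, 112, 22, 29), (57, 3, 17, 26, 3, 8), (16, 1, 4, 10, 1, 0)],
            0.61, missing_rows=["Missing"],
        ),
        _table(
            "breastfeeding",
            ["Breastfed", "Did not breastfeed", "Missing"],
            [(228, 15, 76, 95, 23, 19), (96, 6, 25, 45, 2, 18), (12, 0, 3, 8, 1, 0)],
            0.01, missing_rows=["Missing"],
        ),
        _table(
            "tslb_cat",
            ["0-3 years", "3-5 years", "6-10 years", "11-21 years"],
            [(135, 8, 36, 57, 13, 21), (97, 4, 33, 46, 9, 5),
             (80, 8, 27, 34, 3, 8), (24, 1, 8, 11, 1, 3)],
            0.34,
        ),
        _table(
            "menopause",
            ["No", "Not sure", "Yes", "Missing"],
            [(189, 20, 66, 73, 16, 14), (107, 0, 29, 52, 8, 18),
             (26, 1, 5, 14, 1, 5), (14, 0, 4, 9, 1, 0)],
            0.11, missing_rows=["Missing"],
        ),
        _table(
            "fam_hx",
            ["No", "Yes"],
            [(282, 16, 91, 129, 20, 26), (54, 5, 13, 19, 6, 11)],
            0.04,
        ),
        _table(
            "smoking",
            ["Never", "Former", "Current", "Missing"],
            [(207, 12, 70, 87, 16, 22), (108, 8, 27, 51, 8, 14),
             (6, 0, 3, 2, 0, 1), (15, 1, 4, 8, 2, 0)],
            0.67, missing_rows=["Missing"],
        ),
        _table(
            "alcohol",
            ["Never or former", "Current", "Missing"],
            [(94, 4, 26, 44, 3, 17), (226, 16, 74, 95, 21, 20), (16, 1, 4, 9, 2, 0)],
            0.06, missing_rows=["Missing"],
        ),
        _table(
            "bmi_cat",
            ["16.6-20.9", "21-24.9", "25-47.5", "Missing"],
            [(70, 7, 25, 21, 5, 12), (155, 8, 50, 72, 11, 14),
             (99, 6, 26, 47, 9, 11), (12, 0, 3, 8, 1, 0)],
            0.28, missing_rows=["Missing"],
        ),
        _table(
            "race",
            ["White", "Non-White", "Missing"],
            [(303, 20, 94, 133, 22, 34), (28, 1, 10, 10, 4, 3), (5, 0, 0, 5, 0, 0)],
            0.25, missing_rows=["Missing"],
        ),
        _table(
            "ethnicity",
            ["No", "Yes", "Missing"],
            [(312, 19, 101, 132, 24, 36), (19, 2, 2, 12, 2, 1), (5, 0, 1, 4, 0, 0)],
            0.24, missing_rows=["Missing"],
        ),
        _table(
            "n_roi",
            ["1", "2", "3", "4+"],
            [(63, 8, 24, 24, 5, 2), (119, 9, 37, 53, 8, 12),
             (143, 4, 42, 62, 12, 23), (11, 0, 1, 9, 1, 0)],
            0.1,
        ),
    ]
    return {t.name: t for t in tables}


#: Printed mean (SD) rows (Kruskal-Wallis p across the four named subtypes).
CONTINUOUS_SUMMARIES = {
    "age_dx": {"mean": 36.6, "sd": 3.06, "printed_p": 0.54},
    "tslb": {"mean": 4.44, "sd": 3.96, "printed_p": 0.11},
}
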