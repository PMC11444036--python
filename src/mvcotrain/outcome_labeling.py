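"""Derivation of the severe-hypoglycemia outcome from coded event fields.

Three coded fields describe a candidate hypoglycemia event:

* ``glucose_lt50`` — 1 if blood glucose was below 50 mg/dl, 2 if at or above
  50 mg/dl, 3 if no information is available;
* ``medical_assist`` — 1 if medical assistance was required, 0 if not;
* ``hospital_admit`` — 1 if hospital admission was required, 2 if not,
  3 if no information is available.

An event is labeled SH (severe hypoglycemia) when glucose was below
50 mg/dl and either medical assistance or hospital admission was required.
It is non-SH when glucose was at or above 50 mg/dl with no assistance and no
admission.  Every other combination — including any with missing
information — is Unknown: combinations the SH/non-SH definitions do not
cover verbatim are deliberately left out of the labeled set rather than
guessed, which keeps the labeled classes clean at the cost of a larger
unlabeled pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

SH = "SH"
NON_SH = "nonSH"
UNKNOWN_LABEL = "Unknown"

GLUCOSE_CODES = (1, 2, 3)
ASSIST_CODES = (0, 1)
ADMIT_CODES = (1, 2, 3)


@dataclass(frozen=True)
class OutcomeCodes:
    glucose_lt50: int
    medical_assist: int
    hospital_admit: int

    def __post_init__(self) -> None:
        if self.glucose_lt50 not in GLUCOSE_CODES:
            raise ValidationError(
                f"glucose_lt50={self.glucose_lt50!r} not in {GLUCOSE_CODES}"
            )
        if self.medical_assist not in ASSIST_CODES:
            raise ValidationError(
                f"medical_assist={self.medical_assist!r} not in {ASSIST_CODES}"
            )
        if self.hospital_admit not in ADMIT_CODES:
            raise ValidationError(
                f"hospital_admit={self.hospital_admit!r} not in {ADMIT_CODES}"
            )


def derive_outcome(codes: OutcomeCodes) -> str:
    """Map one coded event to ``"SH"``, ``"nonSH"`` or ``"Unknown"``.

    SH and non-SH are mutually exclusive by construction (they require
    glucose codes 1 and 2 respectively); all remaining combinations are
    Unknown.
    """
    if codes.glucose_lt50 == 1 and (codes.medical_assist == 1 or codes.hospital_admit == 1):
        return SH
    if codes.glucose_lt50 == 2 and codes.medical_assist == 0 and codes.hospital_admit == 2:
        return NON_SH
    return UNKNOWN_LABEL


def label_table(
    events: pd.DataFrame,
    subjects: pd.Index | None = None,
    period: int = 1,
) -> pd.Series:
    """Label subjects from an event table.

    Parameters
    ----------
    events:
        Columns ``subject_id``, ``period``, ``glucose_lt50``,
        ``medical_assist``, ``hospital_admit``; one row per subject per
        period.
    subjects:
        Optional universe of subject ids.  Subjects with no event record in
        the requested period are labeled Unknown (they join the unlabeled
        pool).  Defaults to the subjects present in ``events``.
    period:
        Which observation period to label from (default: first).

    Returns
    -------
    pandas.Series
        Label per subject, indexed by subject id.
    """
    required = {"subject_id", "period", "glucose_lt50", "medical_assist", "hospital_admit"}
    missing = required - set(events.columns)
    if missing:
        raise ValidationError(f"events table missing columns: {sorted(missing)}")
    dupes = events.duplicated(subset=["subject_id", "period"])
    if dupes.any():
        key = events.loc[dupes, ["subject_id", "period"]].iloc[0]
        raise ValidationError(
            f"duplicate event record for subject {key['subject_id']!r}, "
            f"period {key['period']!r}"
        )
    in_period = events[events["period"] == period]
    labels = {}
    for _, row in in_period.iterrows():
        codes = OutcomeCodes(
            int(row["glucose_lt50"]), int(row["medical_assist"]), int(row["hospital_admit"])
        )
        labels[row["subject_id"]] = derive_outcome(codes)
    index = subjects if subjects is not None else pd.Index(in_period["subject_id"])
    out = pd.Series(
        [labels.get(s, UNKNOWN_LABEL) for s in index], index=pd.Index(index), dtype=object
    )
    counts = out.value_counts().to_dict()
    logger.info("labeled %d subjects: %s", len(out), counts)
    return out
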