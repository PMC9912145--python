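"""Calendar-month arithmetic.

Months are handled as integer ordinals (pandas Period 'M' ordinals, where
1970-01 is 0) so that relative-month arithmetic is plain integer arithmetic.
"""
from __future__ import annotations

import pandas as pd

#: Ordinal of 2020-03, the first pandemic-restrictions month used by the
#: COVID-era indicator covariate.
COVID_START = pd.Period("2020-03", freq="M").ordinal


def to_ordinal(month: str | pd.Period) -> int:
    """'YYYY-MM' (or a Period) → integer month ordinal."""
    return pd.Period(month, freq="M").ordinal


def to_str(ordinal: int) -> str:
    return str(pd.Period(ordinal=int(ordinal), freq="M"))


def month_of_year(ordinal: int) -> int:
    """1..12 for January..December."""
    return int(ordinal) % 12 + 1


def season(ordinal: int) -> str:
    """Meteorological season of a calendar month."""
    m = month_of_year(ordinal)
    if m in (12, 1, 2):
        return "winter"
    if m in (3, 4, 5):
        return "spring"
    if m in (6, 7, 8):
        return "summer"
    return "autumn"


def days_in_month(ordinal: int) -> int:
    return pd.Period(ordinal=int(ordinal), freq="M").days_in_month
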