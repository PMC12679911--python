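"""Small shared helpers (display rounding, age arithmetic, logging)."""

from __future__ import annotations

import datetime as _dt
import logging
from decimal import Decimal, ROUND_HALF_UP

log = logging.getLogger("herdvigor")


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, as printed herd tables do.

    Python's built-in round() ties to even, which disagrees with how
    quantities like 6.75 calves/sire are conventionally printed (6.8).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def age_in_years(birth_date: _dt.date, on: _dt.date) -> int:
    """Whole-year age on a given date (birthday not yet reached counts down)."""
    years = on.year - birth_date.year
    if (on.month, on.day) < (birth_date.month, birth_date.day):
        years -= 1
    return years


def parse_date(value) -> _dt.date:
    """Coerce an ISO-8601 string / datetime / date to datetime.date."""
    if isinstance(value, _dt.datetime):
        return value.date()
    if isinstance(value, _dt.date):
        return value
    return _dt.date.fromisoformat(str(value))
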