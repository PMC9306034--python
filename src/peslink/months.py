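"""Calendar-month arithmetic on canonical ``YYYY-MM`` strings.

All linkage and outcome logic in this package is monthly; a day-level
date field deliberately does not exist anywhere in the data model.
"""

from __future__ import annotations

import calendar
import re

from .errors import ValidationError

_MONTH_RE = re.compile(r"^(\d{4})[-/](\d{1,2})$")
_NAME_RE = re.compile(r"^([A-Za-z]+)\s+(\d{4})$")
_NAMES = {name.lower(): i
          for i, name in enumerate(calendar.month_abbr) if name}
_NAMES.update({name.lower(): i
               for i, name in enumerate(calendar.month_name) if name})


def parse_month(value) -> str:
    """Coerce a month written in any supported dialect to canonical ``YYYY-MM``.

    Accepts ``2013-12``, ``2013/12``, ``Dec 2013`` and ``December 2013``.
    Raises :class:`ValidationError` for anything else, including
    out-of-range month numbers.
    """
    text = str(value).strip()
    m = _MONTH_RE.match(text)
    if m:
        year, month = int(m.group(1)), int(m.group(2))
    else:
        m = _NAME_RE.match(text)
        if not m or m.group(1).lower() not in _NAMES:
            raise ValidationError(f"unparseable calendar month: {value!r}")
        year, month = int(m.group(2)), _NAMES[m.group(1).lower()]
    if not 1 <= month <= 12:
        raise ValidationError(f"month number out of range in {value!r}")
    return f"{year:04d}-{month:02d}"


def next_calendar_month(month: str) -> str:
    """The month following ``month`` (canonical ``YYYY-MM``), with year rollover."""
    canonical = parse_month(month)
    year, mon = int(canonical[:4]), int(canonical[5:7])
    if mon == 12:
        return f"{year + 1:04d}-01"
    return f"{year:04d}-{mon + 1:02d}"
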