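"""Rule-based recognition and normalization of temporal expressions.

Handles the date styles that actually occur in Chinese EMR narrative:
absolute dates (2008年3月11日, 2008年3月, 2008年, 2008-3-11, 3月11日),
durations (20年, 3个月, 2周), offsets relative to an implicit "now"
(3天前, 去年, 今天), and returns each with its character span, a kind
(absolute_date / duration / relative) and a granularity. Absolute dates
normalize to zero-padded ISO-8601; under-specified dates omit the unknown
parts (2008-03). Calendar-invalid day components (2月30日) are demoted to
month granularity with a warning flag instead of being rejected.
"""

from __future__ import annotations

import calendar
import datetime as dt
import re
from dataclasses import dataclass, replace
from typing import Optional

__all__ = ["TimeExpression", "extract_time", "normalize_time"]

_UNIT_MAP = {
    "年": "year",
    "个月": "month",
    "月": "month",
    "周": "week",
    "天": "day",
    "日": "day",
    "小时": "hour",
}

# Alternation order is significant: longer, more specific patterns first so
# that leftmost non-overlapping matching consumes e.g. 2008年3月11日 whole.
_TIME_RE = re.compile(
    r"(?P<ymd>(?P<y1>\d{4})年(?P<m1>\d{1,2})月(?P<d1>\d{1,2})日)"
    r"|(?P<iso>(?P<y4>\d{4})-(?P<m4>\d{1,2})-(?P<d4>\d{1,2}))"
    r"|(?P<ym>(?P<y2>\d{4})年(?P<m2>\d{1,2})月)"
    r"|(?P<md>(?P<m3>\d{1,2})月(?P<d3>\d{1,2})日)"
    r"|(?P<y>(?P<y3>\d{4})年)"
    r"|(?P<mo>(?P<m5>1[0-2]|[1-9])月)"
    r"|(?P<dur>(?P<mag>\d+(?:\.\d+)?)(?P<unit>个月|小时|[年周天日])(?P<suffix>[前后来])?)"
    r"|(?P<named>今天|昨天|前天|明天|今年|去年|前年)"
)

_NAMED = {
    # name -> (magnitude, unit, direction) offsets from the reference date
    "今天": (0, "day", 0),
    "昨天": (1, "day", -1),
    "前天": (2, "day", -1),
    "明天": (1, "day", +1),
    "今年": (0, "year", 0),
    "去年": (1, "year", -1),
    "前年": (2, "year", -1),
}


@dataclass(frozen=True)
class TimeExpression:
    """One temporal mention inside a segment."""

    raw: str
    span: tuple[int, int]
    kind: str  # absolute_date | duration | relative
    normalized: Optional[str] = None  # ISO for absolute dates
    magnitude: Optional[float] = None  # for duration / relative
    unit: Optional[str] = None  # year|month|week|day|hour
    granularity: str = "day"  # year|month|day|time_of_day
    direction: int = 0  # -1 past, +1 future (relative only)
    warning: bool = False  # calendar-invalid day demoted to month

    @property
    def is_resolved_date(self) -> bool:
        return self.kind == "absolute_date" and self.normalized is not None


def _absolute(raw: str, span: tuple[int, int], y: int,
              m: int | None = None, d: int | None = None) -> TimeExpression:
    warning = False
    granularity = "year"
    if m is not None:
        if not 1 <= m <= 12:
            # month out of range: keep year only
            return TimeExpression(raw, span, "absolute_date",
                                  normalized=f"{y:04d}", granularity="year",
                                  warning=True)
        granularity = "month"
    if d is not None and m is not None:
        if 1 <= d <= calendar.monthrange(y, m)[1]:
            granularity = "day"
        else:
            d = None
            warning = True
    parts = [f"{y:04d}"]
    if m is not None:
        parts.append(f"{m:02d}")
    if d is not None and granularity == "day":
        parts.append(f"{d:02d}")
    return TimeExpression(raw, span, "absolute_date",
                          normalized="-".join(parts),
                          granularity=granularity, warning=warning)


def extract_time(text: str) -> list[TimeExpression]:
    """All non-overlapping temporal matches, left to right.

    Accepts a segment object (anything with a ``.text``) or a plain string.
    """
    if hasattr(text, "text"):
        text = text.text
    out: list[TimeExpression] = []
    for m in _TIME_RE.finditer(text):
        span = (m.start(), m.end())
        raw = m.group(0)
        if m.group("ymd"):
            out.append(_absolute(raw, span, int(m.group("y1")),
                                 int(m.group("m1")), int(m.group("d1"))))
        elif m.group("iso"):
            out.append(_absolute(raw, span, int(m.group("y4")),
                                 int(m.group("m4")), int(m.group("d4"))))
        elif m.group("ym"):
            out.append(_absolute(raw, span, int(m.group("y2")),
                                 int(m.group("m2"))))
        elif m.group("md"):
            # year must come from a reference date at normalization time
            out.append(TimeExpression(
                raw, span, "relative",
                magnitude=None, unit=None, granularity="day",
                normalized=None,
            ))
        elif m.group("y"):
            out.append(_absolute(raw, span, int(m.group("y3"))))
        elif m.group("mo"):
            # bare month-of-year (3月 = March); year from the reference date
            out.append(TimeExpression(raw, span, "relative",
                                      granularity="month"))
        elif m.group("dur"):
            mag = float(m.group("mag"))
            unit = _UNIT_MAP[m.group("unit")]
            suffix = m.group("suffix")
            if suffix == "前":
                out.append(TimeExpression(raw, span, "relative",
                                          magnitude=mag, unit=unit,
                                          direction=-1,
                                          granularity=_gran(unit)))
            elif suffix == "后":
                out.append(TimeExpression(raw, span, "relative",
                                          magnitude=mag, unit=unit,
                                          direction=+1,
                                          granularity=_gran(unit)))
            else:  # plain duration, incl. trailing 来 ("for N years")
                out.append(TimeExpression(raw, span, "duration",
                                          magnitude=mag, unit=unit,
                                          granularity=_gran(unit)))
        else:  # named relative expression
            mag, unit, direction = _NAMED[raw]
            out.append(TimeExpression(raw, span, "relative",
                                      magnitude=float(mag), unit=unit,
                                      direction=direction,
                                      granularity=_gran(unit)))
    return out


def _gran(unit: str) -> str:
    if unit == "year":
        return "year"
    if unit == "month":
        return "month"
    if unit == "hour":
        return "time_of_day"
    return "day"


def _shift_months(d: dt.date, months: int) -> dt.date:
    total = d.year * 12 + (d.month - 1) + months
    y, m = divmod(total, 12)
    day = min(d.day, calendar.monthrange(y, m + 1)[1])
    return dt.date(y, m + 1, day)


def normalize_time(expr: TimeExpression,
                   reference_date: str | dt.date | None = None
                   ) -> TimeExpression:
    """Resolve an expression to calendar form where possible. Idempotent.

    Absolute dates are already zero-padded ISO; relative expressions are
    resolved against ``reference_date`` when given (otherwise returned
    unresolved, still kind=relative); durations are returned unchanged.
    """
    if expr.kind in ("absolute_date", "duration"):
        return expr
    if reference_date is None:
        return expr
    if isinstance(reference_date, str):
        reference_date = dt.date.fromisoformat(reference_date)
    # M月D日 / bare M月 with the year taken from the reference
    m = re.fullmatch(r"(\d{1,2})月(?:(\d{1,2})日)?", expr.raw)
    if m:
        day = int(m.group(2)) if m.group(2) else None
        resolved = _absolute(expr.raw, expr.span, reference_date.year,
                             int(m.group(1)), day)
        return replace(resolved, kind="absolute_date")
    if expr.magnitude is None or expr.unit is None:
        return expr
    n = expr.magnitude * expr.direction
    if expr.unit == "year":
        target = _shift_months(reference_date, int(round(n)) * 12)
        norm = f"{target.year:04d}" if expr.granularity == "year" \
            else target.isoformat()
    elif expr.unit == "month":
        target = _shift_months(reference_date, int(round(n)))
        norm = target.isoformat()
    else:
        days = {"week": 7, "day": 1, "hour": 1 / 24}[expr.unit] * n
        target = reference_date + dt.timedelta(days=days)
        norm = target.isoformat()
    return replace(expr, kind="absolute_date", normalized=norm)
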