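"""Small time-unit helpers: SI seconds internally, human units at the edges."""

from __future__ import annotations

import re

__all__ = ["to_seconds", "humanize_seconds", "parse_duration"]

_UNIT_SECONDS = {"ms": 1e-3, "s": 1.0, "min": 60.0, "hr": 3600.0, "h": 3600.0}

_DURATION_RE = re.compile(r"^\s*([0-9eE+.\-]+)\s*(ms|s|min|hr|h)?\s*$")


def to_seconds(value: float, unit: str) -> float:
    """Convert a value in ``ms``/``s``/``min``/``hr`` to seconds."""
    try:
        return value * _UNIT_SECONDS[unit.strip()]
    except KeyError:
        raise ValueError(f"unknown time unit {unit!r}; "
                         f"expected one of {sorted(_UNIT_SECONDS)}") from None


def parse_duration(text: str) -> float:
    """Parse ``'300ms'``, ``'5 min'``, ``'2hr'`` or a bare number (seconds)."""
    m = _DURATION_RE.match(text)
    if not m:
        raise ValueError(f"cannot parse duration {text!r}")
    value = float(m.group(1))
    return to_seconds(value, m.group(2) or "s")


def humanize_seconds(seconds: float) -> str:
    """Render a duration with an auto-scaled unit (ms/s/min/hr)."""
    if seconds < 1.0:
        return f"{seconds * 1e3:.3g} ms"
    if seconds < 120.0:
        return f"{seconds:.3g} s"
    if seconds < 7200.0:
        return f"{seconds / 60.0:.3g} min"
    return f"{seconds / 3600.0:.4g} hr"
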