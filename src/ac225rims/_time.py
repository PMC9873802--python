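"""Time-axis conventions.

All internal timestamps are floating-point seconds on the POSIX axis; every
public file interface speaks ISO-8601.  Naive timestamps are taken as UTC.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["to_seconds", "to_iso"]


def to_seconds(t) -> float:
    """ISO-8601 string / datetime / numeric → seconds since the epoch."""
    if isinstance(t, (int, float)):
        return float(t)
    ts = pd.Timestamp(t)
    if ts.tzinfo is not None:
        ts = ts.tz_convert("UTC").tz_localize(None)
    return ts.value / 1e9


def to_iso(seconds: float) -> str:
    """Seconds since the epoch → ISO-8601 string (UTC, second resolution)."""
    return pd.Timestamp(seconds, unit="s").isoformat()
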