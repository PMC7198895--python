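"""Small unit conversions for physiological rates."""

from __future__ import annotations

__all__ = ["rate_per_minute_to_hz", "hz_to_rate_per_minute"]


def rate_per_minute_to_hz(per_minute: float) -> float:
    """Convert a per-minute rate (breaths/min, beats/min) to Hz.

    E.g. 14.7 breaths per minute is 0.245 Hz.
    """
    return per_minute / 60.0


def hz_to_rate_per_minute(hz: float) -> float:
    """Convert a frequency in Hz to a per-minute rate."""
    return hz * 60.0
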