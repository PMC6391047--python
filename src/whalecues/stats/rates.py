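"""Elementary behavioural observables."""

from __future__ import annotations

__all__ = ["time_in_zone", "respiratory_rate"]


def time_in_zone(
    entry_minute: float | None,
    exit_minute: float | None = None,
    trial_length: float = 22.0,
) -> float:
    """Minutes a whale group spent inside an exposure zone.

    ``entry_minute=None`` means the group never entered (returns 0).  A group
    present when the trial ended gets ``exit_minute=trial_length``; a group
    present throughout scores the full trial length.
    """
    if entry_minute is None:
        return 0.0
    if exit_minute is None:
        exit_minute = trial_length
    if entry_minute < 0 or exit_minute > trial_length:
        raise ValueError(
            f"entry/exit must lie within [0, {trial_length}], "
            f"got ({entry_minute}, {exit_minute})"
        )
    if exit_minute < entry_minute:
        raise ValueError(f"exit ({exit_minute}) before entry ({entry_minute})")
    return float(exit_minute - entry_minute)


def respiratory_rate(
    blow_count: float, group_size: int, observed_minutes: float
) -> float:
    """Blows per whale per minute: blow_count / (group_size * observed_minutes)."""
    if group_size < 1:
        raise ValueError(f"group_size must be >= 1, got {group_size}")
    if observed_minutes <= 0:
        raise ValueError("observed_minutes must be > 0 (rate undefined otherwise)")
    if blow_count < 0:
        raise ValueError("blow_count must be >= 0")
    return float(blow_count) / (group_size * observed_minutes)
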