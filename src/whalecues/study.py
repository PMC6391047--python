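"""Small field-protocol arithmetic used when working from published summaries.

When raw trial logs are unavailable, occurrence tables and effect summaries
must be reconstructed from printed percentages and group totals; these
helpers keep that arithmetic explicit and testable.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "occurrence_count",
    "occurrence_table",
    "mean_group_size",
    "fresh_prey_equivalent",
]


def occurrence_count(percent: float, n_groups: int) -> int:
    """Number of groups displaying a behaviour, from a printed percentage.

    The reconstruction is only accepted when the percentage corresponds to an
    integer count (within +/- 0.1 percentage points, allowing for the loose
    rounding conventions of printed summaries).
    """
    k = percent / 100.0 * n_groups
    k_round = int(round(k))
    if abs(k_round / n_groups * 100.0 - percent) > 0.1 + 1e-9:
        raise ValueError(
            f"{percent}% of {n_groups} groups is not an integer count "
            f"(closest: {k_round} -> {k_round / n_groups * 100.0:.2f}%)"
        )
    return k_round


def occurrence_table(
    percent_stim: float, n_stim: int, percent_ctl: float, n_ctl: int
) -> np.ndarray:
    """2x2 displayed/not-displayed table from printed occurrence percentages."""
    k1 = occurrence_count(percent_stim, n_stim)
    k2 = occurrence_count(percent_ctl, n_ctl)
    return np.array([[k1, n_stim - k1], [k2, n_ctl - k2]])


def mean_group_size(total_individuals: int, n_groups: int) -> float:
    """Average whales per group from campaign totals."""
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    return total_individuals / n_groups


def fresh_prey_equivalent(dry_mass_kg: float, moisture_fraction: float) -> float:
    """Fresh-prey mass whose dry matter equals ``dry_mass_kg``.

    Krill is ~80% water, so 4 kg of dry hydrolysate corresponds to the dry
    matter of 4 / (1 - 0.8) = 20 kg of fresh krill.
    """
    if not 0.0 <= moisture_fraction < 1.0:
        raise ValueError("moisture_fraction must lie in [0, 1)")
    if dry_mass_kg < 0:
        raise ValueError("dry_mass_kg must be >= 0")
    return dry_mass_kg / (1.0 - moisture_fraction)
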