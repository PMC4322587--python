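"""Peak breeding/birth month and season from monthly event counts.

Seasonal reproduction is assessed on the month of the event (birth or
estimated conception of a litter), because birth dates are exact but
conception dates are back-calculated and day-level precision would be
spurious.  The peak month is the month with the most events; the peak
season extends outward from the peak through consecutive months that hold
either at least one third as many events as the peak month or at least 20%
of all events — a deliberately conservative rule that trims sparse tails
which would otherwise stretch the apparent season.

Months are numbered 1-12 (January-December) and the calendar is circular:
a December-January peak season wraps across the year boundary.
"""

from __future__ import annotations

from typing import Sequence

SEASON_PEAK_FRACTION = 1 / 3   # month kept if count >= peak_count / 3 ...
SEASON_TOTAL_FRACTION = 0.20   # ... or count >= 20% of all events


def month_histogram(months: Sequence[int]) -> list[int]:
    """Counts per calendar month (index 0 = January) from month numbers."""
    counts = [0] * 12
    for m in months:
        if not 1 <= int(m) <= 12:
            raise ValueError(f"month out of range: {m}")
        counts[int(m) - 1] += 1
    return counts


def peak_month(counts: Sequence[int]) -> int:
    """Month (1-12) holding the most events.

    Ties are broken in favour of the tied month whose two circular
    neighbours hold the most events (the centre of the heaviest local
    mass), then the smallest month number.
    """
    if len(counts) != 12:
        raise ValueError("need 12 monthly counts")
    if sum(counts) <= 0:
        raise ValueError("empty histogram has no peak month")
    best = max(counts)
    tied = [i for i, c in enumerate(counts) if c == best]
    if len(tied) > 1:
        neighbor = {i: counts[(i - 1) % 12] + counts[(i + 1) % 12] for i in tied}
        top = max(neighbor.values())
        tied = [i for i in tied if neighbor[i] == top]
    return min(tied) + 1


def peak_season(counts: Sequence[int]) -> list[int]:
    """Ascending month numbers of the contiguous peak season.

    Starting at the peak month, months are added one at a time in each
    circular direction while they pass the inclusion rule (at least one
    third of the peak-month count, or at least 20% of total events);
    expansion in a direction stops at the first failing month.
    """
    p = peak_month(counts) - 1
    total = sum(counts)
    peak_count = counts[p]

    def keep(i: int) -> bool:
        return (counts[i] >= peak_count * SEASON_PEAK_FRACTION
                or counts[i] >= SEASON_TOTAL_FRACTION * total)

    members = {p}
    for step in (-1, +1):
        i = p
        for _ in range(11):
            i = (i + step) % 12
            if i in members or not keep(i):
                break
            members.add(i)
            if len(members) == 12:
                break
    return sorted(m + 1 for m in members)


def format_season(months: Sequence[int], pattern: str) -> str:
    """Serialize a month set: ``"0"`` for non-seasonal taxa, else e.g. ``"4.5.6"``."""
    if pattern == "NS":
        return "0"
    return ".".join(str(m) for m in sorted(months))
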