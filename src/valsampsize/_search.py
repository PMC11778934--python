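"""Minimal-n integer search on a monotone criterion."""

from __future__ import annotations

from typing import Callable

MAX_N = 100_000_000


def smallest_n(meets_target: Callable[[int], bool], floor: int) -> int:
    """Smallest integer ``n >= floor`` with ``meets_target(n)`` true.

    ``meets_target`` must be monotone (once true, true for all larger n).
    Bracketing by doubling, then bisection; raises if no n up to ``MAX_N``
    satisfies the criterion.
    """
    if meets_target(floor):
        return floor
    lo, hi = floor, floor * 2
    while not meets_target(hi):
        lo, hi = hi, hi * 2
        if hi > MAX_N:
            raise ValueError(
                f"no sample size up to {MAX_N} meets the precision target; "
                "the target is unattainable under the stated assumptions"
            )
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if meets_target(mid):
            hi = mid
        else:
            lo = mid
    return hi
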