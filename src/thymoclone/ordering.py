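"""Temporal ordering of somatic lesions relative to TCRβ rearrangement,
and somatic-rate estimators.

An oligoclonal tumor is a mixture of clones, each defined by a distinct
TCRβ rearrangement.  A lesion carried by a larger share of tumor DNA than
any single clone — indeed by roughly the union of all clones — must have
arisen in a common ancestor *before* the rearrangements that individuate
the clones.  Conversely a lesion whose cell fraction fits inside one
clone is consistent with arising after rearrangement.  The rule compares
the lesion's DNA fraction ``f_L`` to the clone-fraction vector with a
noise tolerance τ:

    pre_rearrangement   if  f_L ≥ Σ clones − τ  and  f_L > max clone + τ
    post_rearrangement  if  f_L ≤ max clone + τ
    indeterminate       otherwise

The rate estimators are simple quotients: somatic point mutations per
megabase of callable sequence, and distinct contributing clones per day
over an observation window (the 9→20 week window is 77 days).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

PRE_REARRANGEMENT = "pre_rearrangement"
POST_REARRANGEMENT = "post_rearrangement"
INDETERMINATE = "indeterminate"

DEFAULT_TOLERANCE = 0.05
#: 9 wk → 20 wk after birth, in days (11 weeks).
DEFAULT_WINDOW_DAYS = 77.0


@dataclass(frozen=True)
class LesionTimingCall:
    """Verdict of the lesion-fraction vs clone-fraction ordering rule."""

    lesion_id: str
    lesion_cell_fraction: float
    clone_fractions: tuple[float, ...]
    sum_clone_fraction: float
    max_clone_fraction: float
    tolerance: float
    verdict: str

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["clone_fractions"] = list(self.clone_fractions)
        return d


def order_lesion(
    lesion_fraction: float,
    clone_fractions: Sequence[float],
    tolerance: float = DEFAULT_TOLERANCE,
    lesion_id: str = "lesion",
) -> LesionTimingCall:
    """Apply the ordering rule to one lesion.

    ``lesion_fraction`` is the fraction of tumor DNA (or cells) carrying the
    lesion; ``clone_fractions`` are the TCRβ clone read fractions of the
    tumor's constituent clones.  The boundary case f_L = max clone is
    post_rearrangement (containable within one clone).
    """
    if not 0 < lesion_fraction <= 1:
        raise ValueError("lesion_fraction must be in (0, 1]")
    fracs = tuple(sorted((float(f) for f in clone_fractions), reverse=True))
    if not fracs:
        raise ValueError("clone_fractions must be nonempty")
    if any(not 0 < f <= 1 for f in fracs):
        raise ValueError("clone fractions must be in (0, 1]")
    total = sum(fracs)
    if total > 1 + tolerance:
        raise ValueError(f"clone fractions sum to {total:g} > 1 + tolerance")
    top = fracs[0]
    if lesion_fraction >= total - tolerance and lesion_fraction > top + tolerance:
        verdict = PRE_REARRANGEMENT
    elif lesion_fraction <= top + tolerance:
        verdict = POST_REARRANGEMENT
    else:
        verdict = INDETERMINATE
    return LesionTimingCall(
        lesion_id=lesion_id,
        lesion_cell_fraction=float(lesion_fraction),
        clone_fractions=fracs,
        sum_clone_fraction=total,
        max_clone_fraction=top,
        tolerance=float(tolerance),
        verdict=verdict,
    )


@dataclass(frozen=True)
class RateEstimates:
    """Somatic mutation and clone-emergence rate estimates with their
    inputs echoed."""

    mutations_per_mb: float | None
    clones_per_day: float | None
    n_mutations: int | None = None
    callable_mb: float | None = None
    n_clones: int | None = None
    window_days: float | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def mutation_rate_per_mb(n_mutations: int, callable_mb: float) -> float:
    """Somatic point-mutation rate: mutations per megabase of callable DNA."""
    if callable_mb <= 0:
        raise ValueError("callable_mb must be positive")
    if n_mutations < 0:
        raise ValueError("n_mutations must be >= 0")
    return n_mutations / callable_mb


def clone_emergence_rate(
    n_clones: int, window_start_days: float, window_end_days: float
) -> float:
    """Distinct tumor-contributing clones produced per day over a window."""
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    if window_end_days <= window_start_days:
        raise ValueError("degenerate window: end must exceed start")
    return n_clones / (window_end_days - window_start_days)


def estimate_rates(
    n_mutations: int | None = None,
    callable_mb: float | None = None,
    n_clones: int | None = None,
    window_days: float | None = DEFAULT_WINDOW_DAYS,
) -> RateEstimates:
    """Bundle both rate estimators; components with missing inputs are
    left None (flagged undefined)."""
    mut = None
    if n_mutations is not None and callable_mb is not None:
        mut = mutation_rate_per_mb(n_mutations, callable_mb)
    clones = None
    if n_clones is not None and window_days is not None:
        clones = clone_emergence_rate(n_clones, 0.0, float(window_days))
    return RateEstimates(
        mutations_per_mb=mut,
        clones_per_day=clones,
        n_mutations=n_mutations,
        callable_mb=callable_mb,
        n_clones=n_clones,
        window_days=window_days,
    )
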