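"""Condition-to-condition D stoichiometry dynamics and writer assignment.

Sites are paired on (ref_id, pos) between two call sets (e.g. siControl
vs. a DUS knockdown); per-site stoichiometry deltas feed a two-sided
paired t-test. Writer (dihydrouridine synthase) assignment picks, per
site, the knockdown producing the largest stoichiometry drop, provided the
drop clears an absolute threshold; ties and sub-threshold drops stay
unassigned — depleting one DUS can be partially compensated by others, so
a forced choice would overstate certainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats


class InsufficientPairsError(ValueError):
    """Fewer than two shared sites between the two conditions."""


@dataclass
class ConditionComparison:
    """One site's stoichiometry in two conditions; delta = b - a."""

    ref_id: str
    pos: int
    fraction_a: float
    fraction_b: float

    @property
    def site(self) -> tuple[str, int]:
        return (self.ref_id, self.pos)

    @property
    def delta(self) -> float:
        return self.fraction_b - self.fraction_a


@dataclass
class PairedResult:
    comparisons: list[ConditionComparison]
    p_value: float
    degenerate: bool = False


def paired_compare(calls_a, calls_b,
                   restrict_to: set[tuple[str, int]] | None = None) -> PairedResult:
    """Pair two call sets on (ref_id, pos) and test deltas with a paired t.

    Accepts SiteCall lists (using their ``d_fraction``) or mappings of
    site -> fraction. Degenerate convention when sd(delta) = 0: p = 1 for
    zero mean delta, p = 0 otherwise (flagged).
    """
    fa = _as_fraction_map(calls_a)
    fb = _as_fraction_map(calls_b)
    shared = sorted(set(fa) & set(fb))
    if restrict_to is not None:
        shared = [s for s in shared if s in restrict_to]
    if len(shared) < 2:
        raise InsufficientPairsError(f"need >= 2 shared sites, got {len(shared)}")
    comparisons = [
        ConditionComparison(ref_id=r, pos=p, fraction_a=fa[(r, p)], fraction_b=fb[(r, p)])
        for r, p in shared
    ]
    deltas = np.array([c.delta for c in comparisons])
    # tolerance absorbs last-ulp noise from the fraction subtractions
    if np.ptp(deltas) < 1e-12:
        degenerate = True
        p = 1.0 if abs(deltas.mean()) < 1e-12 else 0.0
    else:
        degenerate = False
        p = float(stats.ttest_rel([c.fraction_a for c in comparisons],
                                  [c.fraction_b for c in comparisons]).pvalue)
    return PairedResult(comparisons=comparisons, p_value=p, degenerate=degenerate)


def _as_fraction_map(calls) -> dict[tuple[str, int], float]:
    if isinstance(calls, Mapping):
        return {k: float(v) for k, v in calls.items()}
    out = {}
    for c in calls:
        if c.d_fraction is not None:
            out[(c.ref_id, c.pos)] = float(c.d_fraction)
    return out


@dataclass
class WriterAssignment:
    site: tuple[str, int]
    writer: str          # candidate name or "unassigned"
    drop: float          # largest stoichiometry drop observed
    tie: bool = False


def assign_writer(comparisons: Mapping[str, Iterable[ConditionComparison]],
                  drop_threshold: float = 0.10) -> dict[tuple[str, int], WriterAssignment]:
    """Assign each site to the writer whose knockdown drops it the most.

    ``comparisons`` maps candidate name -> ConditionComparison list where
    ``fraction_a`` is the control and ``fraction_b`` the knockdown, so the
    drop at a site is -delta. A site is assigned only when its largest
    drop strictly exceeds ``drop_threshold`` and is unique; exact ties are
    left "unassigned" with a tie flag.
    """
    if not comparisons:
        raise ValueError("empty comparison map")
    drops: dict[tuple[str, int], dict[str, float]] = {}
    for writer, comps in comparisons.items():
        for c in comps:
            drops.setdefault(c.site, {})[writer] = -c.delta
    out: dict[tuple[str, int], WriterAssignment] = {}
    for site, by_writer in sorted(drops.items()):
        best = max(by_writer.values())
        winners = [w for w, d in by_writer.items() if d == best]
        if best > drop_threshold and len(winners) == 1:
            out[site] = WriterAssignment(site=site, writer=winners[0], drop=best)
        else:
            out[site] = WriterAssignment(
                site=site, writer="unassigned", drop=best,
                tie=len(winners) > 1 and best > drop_threshold,
            )
    return out
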