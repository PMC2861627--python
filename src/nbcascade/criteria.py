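"""Genotype expression-profile criteria and the window matcher.

Each genotype's reported expression profile is encoded as an ordered list
of genes whose expression windows must appear in that onset order.  A
window is the span from a gene's first to its last ON step; brief interior
OFF gaps do not split it.  The matcher enforces:

* clamped genes hold their clamp (overexpressed: ON at every step; null:
  never ON), and genes absent from the profile are never expressed;
* onsets are non-decreasing along the listed order, strictly increasing
  for the few pairs where the experimental record shows a clean succession
  rather than overlapping onsets;
* offsets are likewise ordered, except that a window still open at the end
  of the simulation is right-censored and unconstrained;
* every listed gene other than the last must switch off at least once
  after its onset (the window ends within the observation);
* no two expressed genes may occupy an identical window (the distinctness
  condition);
* the final listed gene must persist to the end of the simulation wherever
  nothing remains to shut it off.

The criteria ship as a reviewable JSON fixture (``data/criteria.json``)
rather than code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

from .boolean import BooleanTrajectory
from .network import GENOTYPES, GenotypeSpec

_PROFILE_GENES = ("hb", "Kr", "pdm", "cas")


@dataclass(frozen=True)
class ProfileCriterion:
    genotype: GenotypeSpec
    ordered: tuple[str, ...]
    strict_pairs: frozenset[tuple[str, str]]
    persist: bool

    @property
    def forbidden(self) -> tuple[str, ...]:
        """Genes that must never be expressed (profile complement)."""
        out = []
        for g in _PROFILE_GENES:
            if g in self.ordered:
                continue
            if g == self.genotype.gene and self.genotype.mode == "oe":
                continue
            out.append(g)
        return tuple(out)


def _load() -> dict[str, ProfileCriterion]:
    raw = json.loads(
        resources.files("nbcascade.data").joinpath("criteria.json").read_text()
    )
    table = {}
    for row in raw["criteria"]:
        spec = GenotypeSpec.from_name(row["genotype"])
        table[spec.name] = ProfileCriterion(
            genotype=spec,
            ordered=tuple(row["ordered"]),
            strict_pairs=frozenset(tuple(p) for p in row["strict_pairs"]),
            persist=bool(row["persist"]),
        )
    return table


_CRITERIA: dict[str, ProfileCriterion] | None = None


def criterion_for(genotype: GenotypeSpec | str) -> ProfileCriterion:
    global _CRITERIA
    if _CRITERIA is None:
        _CRITERIA = _load()
    name = genotype if isinstance(genotype, str) else genotype.name
    try:
        return _CRITERIA[name]
    except KeyError:
        raise KeyError(f"no profile criterion for genotype {name!r}") from None


def all_criteria() -> tuple[ProfileCriterion, ...]:
    return tuple(criterion_for(g) for g in GENOTYPES)


def matches(trajectory: BooleanTrajectory,
            criterion: ProfileCriterion) -> bool:
    """Pure predicate: does the trajectory satisfy the profile criterion?"""
    t_end = len(trajectory) - 1
    win = {g: trajectory.window(g) for g in _PROFILE_GENES}
    geno = criterion.genotype

    if not geno.is_wt:
        first, last, n_on = win[geno.gene]
        if geno.mode == "oe" and n_on != t_end + 1:
            return False
        if geno.mode == "loss" and n_on != 0:
            return False
    for g in criterion.forbidden:
        if win[g][2] != 0:
            return False
    for g in criterion.ordered:
        if win[g][2] == 0:
            return False
    for a, b in zip(criterion.ordered[:-1], criterion.ordered[1:]):
        if (a, b) in criterion.strict_pairs:
            if win[a][0] >= win[b][0]:
                return False
        elif win[a][0] > win[b][0]:
            return False
        if win[a][1] != t_end and win[a][1] > win[b][1]:
            return False
    if criterion.persist and win[criterion.ordered[-1]][1] != t_end:
        return False
    # every non-final listed gene must switch off at least once after its
    # onset (late re-expression is tolerated; never ending is not)
    clamped_on = geno.gene if geno.mode == "oe" else None
    for g in criterion.ordered[:-1]:
        if g == clamped_on:
            continue
        first, last, n_on = win[g]
        if last == t_end and n_on == t_end - first + 1:
            return False
    expressed = [g for g in _PROFILE_GENES if win[g][2] > 0]
    for i, a in enumerate(expressed):
        for b in expressed[i + 1:]:
            if win[a][:2] == win[b][:2]:
                return False
    return True
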