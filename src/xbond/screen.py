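"""Wild-type-referenced screening of candidate mutants by key distances.

A candidate enzyme-substrate complex passes the screen iff *both* catalytic
key distances (D_C8-SG and D_N1-HZ) are strictly shorter, on mean, than the
corresponding wild-type reference distances.  Shorter distances indicate a
binding conformation more conducive to nucleophilic attack and transition-
state stabilization, hence a candidate more likely to turn the substrate
over.  The verdict deliberately uses means only — spreads are carried along
for reporting but never enter the rule; an optional margin factor ``k``
tightens the rule to mean + k*SD < reference mean for conservative screening.
"""

from __future__ import annotations

from dataclasses import dataclass

from .analysis import DistanceSummary
from .errors import SpecificationError

__all__ = ["ScreenReference", "ScreenResult", "screen", "rank_candidates"]


@dataclass(frozen=True)
class ScreenReference:
    """The wild-type key-distance summaries one substrate context."""

    label: str
    summaries: tuple[DistanceSummary, DistanceSummary]


@dataclass(frozen=True)
class ScreenResult:
    """One candidate's verdict against a reference."""

    candidate_label: str
    reference_label: str
    candidate_summaries: tuple[DistanceSummary, DistanceSummary]
    criteria: dict[str, bool]  # per-distance-label boolean
    verdict: str  # "pass" | "fail"

    @property
    def passed(self) -> bool:
        return self.verdict == "pass"


def screen(
    candidate: tuple[DistanceSummary, DistanceSummary],
    reference: ScreenReference,
    candidate_label: str = "candidate",
    margin_k: float = 0.0,
) -> ScreenResult:
    """Apply the WT-referenced rule: pass iff both means strictly shorter.

    Candidate and reference summaries are matched by distance label; a label
    mismatch is a specification error.  ``margin_k`` > 0 requires
    candidate mean + k*SD < reference mean instead (default 0: means only).
    """
    ref_by_label = {s.label: s for s in reference.summaries}
    cand_labels = [s.label for s in candidate]
    if sorted(cand_labels) != sorted(ref_by_label):
        raise SpecificationError(
            f"candidate distance labels {sorted(cand_labels)} do not match "
            f"reference labels {sorted(ref_by_label)}"
        )
    criteria = {
        s.label: (s.mean + margin_k * s.sd) < ref_by_label[s.label].mean
        for s in candidate
    }
    verdict = "pass" if all(criteria.values()) else "fail"
    return ScreenResult(
        candidate_label=candidate_label,
        reference_label=reference.label,
        candidate_summaries=tuple(candidate),
        criteria=criteria,
        verdict=verdict,
    )


def rank_candidates(results: list[ScreenResult]) -> list[ScreenResult]:
    """Order results: passes first, each group by ascending sum of the two
    candidate means, ties broken lexicographically by candidate label."""
    if not results:
        raise SpecificationError("no screen results to rank")

    def key(r: ScreenResult) -> tuple:
        total = sum(s.mean for s in r.candidate_summaries)
        return (0 if r.passed else 1, total, r.candidate_label)

    return sorted(results, key=key)
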