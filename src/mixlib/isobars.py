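"""Cross-mix disambiguation of isobars.

Compounds of one mix whose adduct-ion m/z values fall within the precursor
isolation window (1 Da) of each other produce indistinguishable extracted
ion chromatograms and DDA precursors, so a chromatographic peak cannot be
attributed to a compound by mass alone.  Because the same substance recurs
in several mixes, a mix in which it is the *only* member of its isolation
group anchors its retention time; anchors propagate across mixes and can
leave exactly one peak for exactly one remaining compound, which is then
assigned by elimination.  Unresolvable many-to-many cases keep a tentative
(level 3) identification and their spectra are excluded from the library;
anchored/eliminated unique assignments are confirmed (level 1).

Grouping uses the transitive closure of pairwise |delta m/z| <= window, so
a chain of isobars separated by less than the window each ends up in one
group even if its extremes differ by more.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .chem import Adduct, get_adduct
from .msio import CompoundEntry, MixDesign
from .prescreen import ChromPeak

__all__ = [
    "IsobarGroup",
    "Assignment",
    "group_isobars",
    "resolve",
    "filter_records",
]

LEVEL_CONFIRMED = "1"
LEVEL_TENTATIVE = "3"
NOT_DETECTED = "not_detected"

ISOLATION_WINDOW_DA = 1.0


@dataclass(frozen=True)
class IsobarGroup:
    """Mix members that co-fall within one precursor isolation window."""

    mix: str
    members: Tuple[str, ...]  # compound identifiers, sorted
    mz_min: float
    mz_max: float

    def __post_init__(self):
        if not self.members:
            raise ValueError("isobar group needs at least one member")


@dataclass(frozen=True)
class Assignment:
    compound_id: str
    mix: str
    level: str  # "1" | "3" | "not_detected"
    rationale: str  # alone_in_mix | anchored_elsewhere | by_elimination |
    #                 ambiguous | no_peak
    rt: Optional[float] = None  # minutes
    peak: Optional[ChromPeak] = None


def group_isobars(design: MixDesign,
                  compounds: Mapping[str, CompoundEntry],
                  adduct: Adduct | str,
                  window_da: float = ISOLATION_WINDOW_DA
                  ) -> List[IsobarGroup]:
    """Connected components of |delta ion m/z| <= window within each mix."""
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    groups: List[IsobarGroup] = []
    for mix in sorted(design.mixes):
        members = sorted(design.compounds_in(mix))
        if not members:
            continue
        with_mz = sorted(
            ((compounds[cid].ion_mz(adduct), cid) for cid in members),
        )
        component: List[Tuple[float, str]] = [with_mz[0]]
        for item in with_mz[1:]:
            if item[0] - component[-1][0] <= window_da:
                component.append(item)
            else:
                groups.append(_make_group(mix, component))
                component = [item]
        groups.append(_make_group(mix, component))
    return groups


def _make_group(mix: str, component: Sequence[Tuple[float, str]]) -> IsobarGroup:
    return IsobarGroup(
        mix=mix,
        members=tuple(sorted(cid for _, cid in component)),
        mz_min=component[0][0],
        mz_max=component[-1][0],
    )


def resolve(groups: Sequence[IsobarGroup],
            detections: Mapping[IsobarGroup, Sequence[ChromPeak]],
            rt_tol: float = 0.5) -> List[Assignment]:
    """Assign peaks to compounds by retention-time anchoring across mixes.

    Per group: a solo member with one peak is confirmed and anchors its RT;
    anchored members claim in-tolerance peaks in every other mix; when one
    unclaimed peak and one unanchored member remain, the member is
    confirmed by elimination (which may anchor it for further mixes, so the
    procedure iterates to a fixpoint).  Peaks claimed by two anchors
    (co-elution) demote both claimants to level 3; remaining many-to-many
    cases are level 3; members with no peak left are not detected.
    """
    if rt_tol <= 0:
        raise ValueError("rt_tol must be positive")
    anchors: Dict[str, float] = {}
    #: first confirming assignment per (compound, mix); keeps the original
    #: rationale (e.g. by_elimination) across later fixpoint passes
    confirmed: Dict[Tuple[str, str], Assignment] = {}
    ordered = sorted(groups, key=lambda g: (g.mix, g.members))
    # fixpoint over anchor propagation
    while True:
        added = False
        for group in ordered:
            for assignment in _resolve_group(
                    group, list(detections.get(group, ())), anchors, rt_tol):
                if assignment.level != LEVEL_CONFIRMED:
                    continue
                key = (assignment.compound_id, assignment.mix)
                if key not in confirmed:
                    confirmed[key] = assignment
                if (assignment.rt is not None
                        and assignment.compound_id not in anchors):
                    anchors[assignment.compound_id] = assignment.rt
                    added = True
        if not added:
            break
    out: List[Assignment] = []
    for group in ordered:
        for assignment in _resolve_group(
                group, list(detections.get(group, ())), anchors, rt_tol):
            key = (assignment.compound_id, assignment.mix)
            if assignment.level == LEVEL_CONFIRMED and key in confirmed:
                # later passes re-derive the same peak via the anchor; keep
                # the rationale that first confirmed it.  Demotions (level
                # 3) computed at the fixpoint win over earlier confirmation.
                assignment = confirmed[key]
            out.append(assignment)
    return out


def _resolve_group(group: IsobarGroup, peaks: List[ChromPeak],
                   anchors: Mapping[str, float], rt_tol: float
                   ) -> List[Assignment]:
    # members with the same formula share one EIC, so the same physical
    # peak may be listed once per member; value-identical peaks collapse
    peaks = sorted(set(peaks), key=lambda p: p.rt)
    members = list(group.members)

    def make(cid, level, rationale, peak=None):
        return Assignment(compound_id=cid, mix=group.mix, level=level,
                          rationale=rationale,
                          rt=peak.rt if peak else None, peak=peak)

    if not peaks:
        return [make(cid, NOT_DETECTED, "no_peak") for cid in members]

    if len(members) == 1:
        cid = members[0]
        if len(peaks) == 1:
            return [make(cid, LEVEL_CONFIRMED, "alone_in_mix", peaks[0])]
        if cid in anchors:
            near = [p for p in peaks if abs(p.rt - anchors[cid]) <= rt_tol]
            if len(near) == 1:
                return [make(cid, LEVEL_CONFIRMED, "anchored_elsewhere",
                             near[0])]
        return [make(cid, LEVEL_TENTATIVE, "ambiguous")]

    # multi-member group: anchored members claim in-tolerance peaks
    claims: Dict[int, List[str]] = {}
    for cid in members:
        if cid in anchors:
            near = [(abs(p.rt - anchors[cid]), i)
                    for i, p in enumerate(peaks)
                    if abs(p.rt - anchors[cid]) <= rt_tol]
            if near:
                _, idx = min(near)
                claims.setdefault(idx, []).append(cid)
    assignments: Dict[str, Assignment] = {}
    claimed_idx = set()
    for idx, claimants in sorted(claims.items()):
        claimed_idx.add(idx)
        if len(claimants) == 1:
            cid = claimants[0]
            assignments[cid] = make(cid, LEVEL_CONFIRMED,
                                    "anchored_elsewhere", peaks[idx])
        else:
            # co-elution of two anchored compounds: safety over coverage
            for cid in claimants:
                assignments[cid] = make(cid, LEVEL_TENTATIVE, "ambiguous")
    unclaimed = [p for i, p in enumerate(peaks) if i not in claimed_idx]
    remaining = [cid for cid in members if cid not in assignments
                 and cid not in anchors]
    # anchored members whose anchor matched no peak here: not detected
    for cid in members:
        if cid in anchors and cid not in assignments:
            assignments[cid] = make(cid, NOT_DETECTED, "no_peak")
    if len(remaining) == 1 and len(unclaimed) == 1:
        cid = remaining[0]
        assignments[cid] = make(cid, LEVEL_CONFIRMED, "by_elimination",
                                unclaimed[0])
    elif not unclaimed:
        for cid in remaining:
            assignments[cid] = make(cid, NOT_DETECTED, "no_peak")
    else:
        for cid in remaining:
            assignments[cid] = make(cid, LEVEL_TENTATIVE, "ambiguous")
    return [assignments[cid] for cid in members]


def filter_records(spectra: Iterable, assignments: Sequence[Assignment]
                   ) -> Tuple[List, List[str]]:
    """Retain spectra of confirmed (level 1) assignments only.

    ``spectra`` items must expose ``compound_id`` and ``mix`` attributes
    (e.g. :class:`~mixlib.annotate.CleanSpectrum`).  Returns the retained
    spectra and an exclusion log with one entry per dropped spectrum.
    """
    levels = {(a.compound_id, a.mix): a for a in assignments}
    kept: List = []
    log: List[str] = []
    for spectrum in spectra:
        key = (spectrum.compound_id, spectrum.mix)
        assignment = levels.get(key)
        if assignment is not None and assignment.level == LEVEL_CONFIRMED:
            kept.append(spectrum)
        else:
            reason = assignment.rationale if assignment else "unassigned"
            level = assignment.level if assignment else "none"
            log.append(
                f"{spectrum.compound_id}\t{spectrum.mix}\t"
                f"level={level}\treason={reason}"
            )
    return kept, log
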