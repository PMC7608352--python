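"""Deterministic rule-based phenotyping from coded clinical events.

Implements the CVM (congenital cardiovascular malformation) classification
cascade and the neuropsychiatric classification. Each participant receives
exactly one of CASE / CONTROL / EXCLUDED per phenotype, with a
machine-readable reason and the triggering events as evidence.

The CVM cascade, in precedence order:

1. Any syndrome code -> EXCLUDED(SYNDROME): keeps the case group
   non-syndromic.
2. Congenital-circulatory diagnosis codes -> CASE, except that Q21.1
   (shared by atrial septal defect and patent foramen ovale, a normal
   variant) is voided when the record indicates PFO: a PFO-specific
   closure operation (K16.5), or a stroke with no atrial fibrillation at or
   before it occurring strictly before the earliest Q21.1. A participant
   whose only case evidence was voided Q21.1 is EXCLUDED from both groups.
3. Congenital-heart operation codes, self-reported congenital heart
   disease, or self-reported heart surgery before age 18 -> CASE.
4. Aortic-valve disease codes (the bicuspid aortic valve pattern) -> CASE
   when first diagnosed before age 65 and free of endocarditis-type
   exclusions; at >= 65 the valve disease is presumed degenerative and the
   participant is EXCLUDED; with an exclusion diagnosis likewise EXCLUDED.
5. Remaining acquired-defect codes -> EXCLUDED from controls.
6. Otherwise CONTROL.

Cause-of-death (DEATH system) events carry ICD10 codes and run through the
same sets, so deceased participants are classified like living ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .codebook import Codebook, match

__all__ = [
    "ClinicalEvent",
    "PhenotypeAssignment",
    "classify_cvm",
    "classify_neuropsych",
    "cognitive_eligibility",
    "CVM",
    "NEUROPSYCH",
    "CASE",
    "CONTROL",
    "EXCLUDED",
]

CVM = "CVM"
NEUROPSYCH = "NEUROPSYCH"
CASE = "CASE"
CONTROL = "CONTROL"
EXCLUDED = "EXCLUDED"


@dataclass(frozen=True)
class ClinicalEvent:
    """One dated, system-qualified clinical code for a participant.

    Event timing is expressed as age at event (years, possibly fractional);
    ``tiebreak`` orders same-age events when the ordering matters (the
    stroke-before-Q21.1 rule).
    """

    participant_id: str
    system: str  # ICD9 | ICD10 | OPCS4 | SELF_ILLNESS | SELF_OPERATION | DEATH
    code: str
    age_at_event: float
    tiebreak: float = 0.0

    def __post_init__(self):
        if not self.code:
            raise ValueError("code must be non-empty")
        if self.age_at_event < 0:
            raise ValueError("age_at_event must be >= 0")


@dataclass(frozen=True)
class PhenotypeAssignment:
    participant_id: str
    phenotype: str  # CVM | NEUROPSYCH
    status: str  # CASE | CONTROL | EXCLUDED
    reason: str  # enumerated rule id; "" only for CONTROL with no codes
    evidence: tuple = field(default_factory=tuple)


def _check_owner(participant_id: str, events) -> None:
    for ev in events:
        if ev.participant_id != participant_id:
            raise ValueError(
                f"event for {ev.participant_id!r} passed with participant "
                f"{participant_id!r}"
            )


def _q211_voided_as_pfo(events, codebook: Codebook):
    """Return (voided, reason, evidence) for the Q21.1 PFO disambiguation.

    Q21.1 evidence is voided if the participant has a PFO-specific
    operation code, or any stroke with no atrial-fibrillation code at or
    before it that occurs strictly before the earliest Q21.1 event.
    A same-age stroke (identical tiebreak) counts as prior: with no finer
    timing information the conservative reading purges the possible PFO
    from the case group.
    """
    q211 = match(events, codebook["q211"])
    if not q211:
        return False, None, ()
    pfo_ops = match(events, codebook["pfo_ops"])
    if pfo_ops:
        return True, "PFO_K165", tuple(q211 + pfo_ops)
    first_q211 = (q211[0].age_at_event, q211[0].tiebreak)
    af = match(events, codebook["atrial_fibrillation"])
    for stroke in match(events, codebook["stroke"]):
        when = (stroke.age_at_event, stroke.tiebreak)
        if when > first_q211:
            continue
        af_before = any(
            (a.age_at_event, a.tiebreak) <= when for a in af
        )
        if not af_before:
            return True, "PFO_PRIOR_STROKE", tuple(q211 + [stroke])
    return False, None, ()


def classify_cvm(
    participant_id: str, events, codebook: Codebook
) -> PhenotypeAssignment:
    """Classify one participant's CVM status from their event history."""
    _check_owner(participant_id, events)

    syndrome = match(events, codebook["syndrome_exclusions"])
    if syndrome:
        return PhenotypeAssignment(
            participant_id, CVM, EXCLUDED, "SYNDROME", tuple(syndrome)
        )

    voided, pfo_reason, pfo_evidence = _q211_voided_as_pfo(events, codebook)

    congenital = match(events, codebook["congenital_circulatory"])
    if voided:
        q211_patterns = codebook["q211"]
        congenital = [
            ev
            for ev in congenital
            if not any(p.matches(ev.system, ev.code) for p in q211_patterns)
        ]
    if congenital:
        return PhenotypeAssignment(
            participant_id, CVM, CASE, "CONGENITAL_CODE", tuple(congenital)
        )

    ops = match(events, codebook["cvm_ops"])
    if ops:
        return PhenotypeAssignment(participant_id, CVM, CASE, "CVM_OP", tuple(ops))
    self_rep = match(events, codebook["self_report_cvm"])
    if self_rep:
        return PhenotypeAssignment(
            participant_id, CVM, CASE, "SELF_REPORT_CVM", tuple(self_rep)
        )
    surgery = [
        ev
        for ev in match(events, codebook["self_report_heart_surgery"])
        if ev.age_at_event < 18
    ]
    if surgery:
        return PhenotypeAssignment(
            participant_id, CVM, CASE, "HEART_SURGERY_UNDER_18", tuple(surgery)
        )

    bav = match(events, codebook["bav_codes"])
    if bav:
        bav_excl = match(events, codebook["bav_exclusions"])
        if bav_excl:
            return PhenotypeAssignment(
                participant_id, CVM, EXCLUDED, "BAV_EXCLUSION", tuple(bav + bav_excl)
            )
        if bav[0].age_at_event < 65:
            return PhenotypeAssignment(
                participant_id, CVM, CASE, "BAV_UNDER_65", tuple(bav)
            )
        return PhenotypeAssignment(
            participant_id, CVM, EXCLUDED, "BAV_AGE_GE_65", tuple(bav)
        )

    if voided:
        return PhenotypeAssignment(
            participant_id, CVM, EXCLUDED, pfo_reason, pfo_evidence
        )

    ctrl_excl = match(events, codebook["control_exclusions"])
    if ctrl_excl:
        return PhenotypeAssignment(
            participant_id, CVM, EXCLUDED, "CONTROL_EXCLUSION_CODE", tuple(ctrl_excl)
        )
    return PhenotypeAssignment(participant_id, CVM, CONTROL, "")


def classify_neuropsych(
    participant_id: str, events, codebook: Codebook
) -> PhenotypeAssignment:
    """Classify neuropsychiatric status: case codes dominate, any other
    mental/behavioural code excludes the participant from controls."""
    _check_owner(participant_id, events)
    cases = match(events, codebook["neuropsych_cases"])
    if cases:
        return PhenotypeAssignment(
            participant_id, NEUROPSYCH, CASE, "NEUROPSYCH_CODE", tuple(cases)
        )
    other = match(events, codebook["neuropsych_control_exclusions"])
    if other:
        return PhenotypeAssignment(
            participant_id,
            NEUROPSYCH,
            EXCLUDED,
            "NEUROPSYCH_OTHER_F_CODE",
            tuple(other),
        )
    return PhenotypeAssignment(participant_id, NEUROPSYCH, CONTROL, "")


def cognitive_eligibility(participant_id: str, events, codebook: Codebook) -> bool:
    """Whether a participant enters the cognitive-function analyses.

    Participants with any diagnosis code previously associated with the
    deletion (the cognitive_exclusions set) are removed from the whole
    cohort before cognitive testing analyses; CVM status is independent.
    """
    _check_owner(participant_id, events)
    return not match(events, codebook["cognitive_exclusions"])
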