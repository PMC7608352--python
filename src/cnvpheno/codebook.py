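"""Clinical-code sets and pattern matching for the phenotyping cascade.

A codebook maps named code sets to lists of ``"SYSTEM:pattern"`` strings,
where SYSTEM is one of ICD9, ICD10, OPCS4, SELF_ILLNESS, SELF_OPERATION,
and a pattern is either an exact code or a prefix ending in ``*``.
Cause-of-death records (system DEATH) carry ICD10 codes, so ICD10 patterns
also match DEATH-system events.

The shipped default codebook is a documented stand-in assembled from the
public ICD-10/OPCS-4 chapter structure (Q20-Q28 congenital circulatory
codes, I35.x aortic valve disease, K16.5 PFO closure, I63/I64 stroke, I48
atrial fibrillation, F-chapter neuropsychiatric subsets); production use
against real hospital-episode data should supply the study's own curated
lists via :meth:`Codebook.from_yaml`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import yaml

__all__ = ["CodePattern", "Codebook", "match", "default_codebook"]

SYSTEMS = {"ICD9", "ICD10", "OPCS4", "SELF_ILLNESS", "SELF_OPERATION", "DEATH"}

#: Code sets the CVM / neuropsychiatric cascade requires.
REQUIRED_SETS = (
    "syndrome_exclusions",
    "congenital_circulatory",
    "q211",
    "pfo_ops",
    "stroke",
    "atrial_fibrillation",
    "cvm_ops",
    "self_report_cvm",
    "self_report_heart_surgery",
    "bav_codes",
    "bav_exclusions",
    "control_exclusions",
    "neuropsych_cases",
    "neuropsych_control_exclusions",
    "cognitive_exclusions",
)


@dataclass(frozen=True)
class CodePattern:
    system: str
    pattern: str  # exact code, or prefix ending in '*'

    def __post_init__(self):
        if self.system not in SYSTEMS:
            raise ValueError(f"unknown coding system {self.system!r}")
        if not self.pattern:
            raise ValueError("empty code pattern")

    def matches(self, system: str, code: str) -> bool:
        # death certificates are coded in ICD10
        sys_ok = system == self.system or (
            system == "DEATH" and self.system == "ICD10"
        )
        if not sys_ok:
            return False
        if self.pattern.endswith("*"):
            return code.startswith(self.pattern[:-1])
        return code == self.pattern

    @classmethod
    def parse(cls, spec: str) -> "CodePattern":
        system, _, pattern = spec.partition(":")
        return cls(system, pattern)


class Codebook:
    """Named code sets driving the phenotype classification cascade."""

    def __init__(self, sets: dict[str, Sequence[str | CodePattern]]):
        self.sets: dict[str, tuple[CodePattern, ...]] = {}
        for name, patterns in sets.items():
            parsed = tuple(
                p if isinstance(p, CodePattern) else CodePattern.parse(p)
                for p in patterns
            )
            self.sets[name] = parsed
        missing = [s for s in REQUIRED_SETS if s not in self.sets]
        if missing:
            raise ValueError(f"codebook missing required sets: {missing}")

    def __getitem__(self, name: str) -> tuple[CodePattern, ...]:
        return self.sets[name]

    def to_dict(self) -> dict[str, list[str]]:
        return {
            name: [f"{p.system}:{p.pattern}" for p in pats]
            for name, pats in self.sets.items()
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "Codebook":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError("codebook YAML must map set names to pattern lists")
        return cls(data)

    @classmethod
    def default(cls) -> "Codebook":
        return default_codebook()


def match(events: Iterable, code_set: Sequence[CodePattern]) -> list:
    """Return the events matching any pattern, sorted by (age, tiebreak).

    Exact patterns require code equality; ``prefix*`` patterns match any
    code starting with the prefix. The event's coding system must match the
    pattern's (DEATH events match ICD10 patterns).
    """
    hits = [
        ev
        for ev in events
        if any(p.matches(ev.system, ev.code) for p in code_set)
    ]
    hits.sort(key=lambda ev: (ev.age_at_event, ev.tiebreak))
    return hits


def default_codebook() -> Codebook:
    """The shipped stand-in codebook (see module docstring)."""
    neuropsych_cases = [
        "ICD10:F20*",  # schizophrenia
        "ICD10:F25*",  # schizoaffective
        "ICD10:F30*",  # mania
        "ICD10:F31*",  # bipolar disorder
        "ICD10:F7*",   # intellectual disability
        "ICD10:F80*",  # speech/language developmental disorders
        "ICD10:F81*",  # scholastic developmental disorders
        "ICD10:F82*",
        "ICD10:F83*",
        "ICD10:F84*",  # autism spectrum
        "ICD10:F88*",
        "ICD10:F89*",
    ]
    return Codebook(
        {
            "syndrome_exclusions": [
                "ICD10:Q87*",  # congenital malformation syndromes
                "ICD10:Q90*",  # Down syndrome
                "ICD10:Q91*",
                "ICD10:Q93*",
                "ICD10:Q96*",  # Turner syndrome
                "ICD10:Q99*",
                "ICD9:758*",
            ],
            # congenital malformations of the circulatory system
            "congenital_circulatory": [
                "ICD10:Q20*",
                "ICD10:Q21*",
                "ICD10:Q22*",
                "ICD10:Q23*",
                "ICD10:Q24*",
                "ICD10:Q25*",
                "ICD10:Q26*",
                "ICD10:Q27*",
                "ICD10:Q28*",
                "ICD9:745*",
                "ICD9:746*",
                "ICD9:747*",
            ],
            "q211": ["ICD10:Q211"],  # ASD / patent foramen ovale
            "pfo_ops": ["OPCS4:K165"],  # PFO-specific closure operation
            "stroke": ["ICD10:I63*", "ICD10:I64", "ICD9:434*", "ICD9:436"],
            "atrial_fibrillation": ["ICD10:I48*", "ICD9:4273*"],
            # operations commonly associated with congenital heart defects
            "cvm_ops": ["OPCS4:K04*", "OPCS4:K05*", "OPCS4:L23*"],
            "self_report_cvm": ["SELF_ILLNESS:1588"],  # congenital heart disease
            "self_report_heart_surgery": ["SELF_OPERATION:1553"],
            # aortic stenosis / insufficiency / valve replacement (BAV pattern)
            "bav_codes": [
                "ICD10:I350",
                "ICD10:I351",
                "ICD10:I352",
                "ICD9:4241*",
                "OPCS4:K26*",  # aortic valve replacement
                "SELF_ILLNESS:1490",   # aortic stenosis
                "SELF_ILLNESS:1491",   # aortic regurgitation
                "SELF_OPERATION:1100", # aortic valve replacement
            ],
            "bav_exclusions": [
                "ICD10:I33*",  # infective endocarditis
                "ICD10:I38",
                "ICD10:I39*",
                "ICD10:I06*",  # rheumatic aortic valve disease
                "ICD9:421*",
            ],
            # acquired heart defects etc. that disqualify a control
            "control_exclusions": [
                "ICD10:I05*",
                "ICD10:I08*",
                "ICD10:I34*",
                "ICD10:I37*",
            ],
            "neuropsych_cases": neuropsych_cases,
            # any other mental/behavioural code excludes from controls;
            # case codes take precedence in the cascade
            "neuropsych_control_exclusions": ["ICD10:F*"],
            "cognitive_exclusions": list(neuropsych_cases),
        }
    )
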