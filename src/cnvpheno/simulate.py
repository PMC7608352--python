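"""Synthetic biobank cohort generator with ground-truth labels.

Simulates a cohort carrying the full statistical structure the downstream
pipeline assumes: deletion carrier status at a configurable prevalence,
CVM and neuropsychiatric phenotypes whose population odds ratio with
carrier status equals the configured value, coded clinical-event histories
that realize those phenotypes (including deliberate decoys that must be
routed to EXCLUDED by the classifier), PennCNV-style deletion calls with
sample QC metrics, cognitive scores, qualifications and fecundity counts.

Phenotype risks are OR-targeted: given overall prevalence p, carrier
fraction q and odds ratio R, the non-carrier risk p0 solves

    q * p1(p0) + (1 - q) * p0 = p,   with  p1/(1-p1) = R * p0/(1-p0),

so the configured odds ratio is the true population parameter, not just an
expectation over a mixture. CVM and neuropsychiatric status are simulated
independently given carrier status (their joint distribution among carriers
is not identified by the summary statistics the generator targets).

Event timing is encoded as integer age-at-event with a fractional tiebreak
ordering same-age events; background (non-locus) CNVs are placed on
autosomes other than chromosome 15 so only designated carriers intersect
the deletion locus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .cnv import BP1_BP2_LOCUS, GenomicInterval
from .codebook import Codebook

__all__ = [
    "CohortParams",
    "SimulatedCohort",
    "ConfigurationError",
    "simulate_cohort",
    "emit_code_history",
    "simulate_cnv_calls",
    "solve_noncarrier_risk",
]


class ConfigurationError(ValueError):
    """Invalid generator parameter; the message names the field."""


# Baseline (non-carrier) outcome distributions, matched to summary statistics
# typical of a middle-aged volunteer cohort: mean reaction time ~557 ms with
# SD ~110 ms, mean fluid-intelligence score ~6, P(numeric-memory score > 6)
# ~0.55, P(>=1 pairs-matching error) ~0.45.
REACTION_TIME_MEAN = 556.8
REACTION_TIME_SD = 110.0
FLUID_INTELLIGENCE_RATE = 5.99
NUMERIC_MEMORY_BASE_LOGIT = 0.2
PAIRS_MATCHING_BASE_LOGIT = -0.2

#: CVM decoy kinds the event emitter can realize (plus the neuropsychiatric one)
DECOY_KINDS = (
    "pfo_k165",
    "pfo_prior_stroke",
    "bav_age_ge_65",
    "bav_endocarditis",
    "syndrome",
    "neuropsych_other_f",
)


def _default_decoy_rates() -> dict[str, float]:
    return {
        "pfo_k165": 0.002,
        "pfo_prior_stroke": 0.001,
        "bav_age_ge_65": 0.004,
        "bav_endocarditis": 0.001,
        "syndrome": 0.002,
        "neuropsych_other_f": 0.02,
    }


def _default_cognitive_effects() -> dict[str, float]:
    # carrier shifts: slower reaction time (+17.8 ms), lower fluid
    # intelligence (log rate ratio 5.40/5.99), lower odds of a high numeric
    # memory score, higher odds of pairs-matching errors
    return {
        "reaction_time_shift": 17.8,
        "fluid_intelligence_log_rate": math.log(5.40 / 5.99),
        "numeric_memory_log_odds": -0.35,
        "pairs_matching_log_odds": 0.15,
    }


def _default_qualification_probs() -> dict[str, tuple[float, float, float]]:
    # (other, degree, a_levels) shares per carrier group
    return {
        "non_carrier": (0.560, 0.328, 0.112),
        "carrier": (0.669, 0.229, 0.102),
    }


def _default_fecundity_rates() -> dict[str, dict[str, float]]:
    # mean children fathered / live births
    return {
        "male": {"carrier": 1.66, "non_carrier": 1.80},
        "female": {"carrier": 1.88, "non_carrier": 1.82},
    }


def _default_qc_fail_rates() -> dict[str, float]:
    # fractions observed in large array-based CNV-calling campaigns
    return {"waviness": 0.0006, "excess_cnvs": 0.0029}


@dataclass(frozen=True)
class CohortParams:
    """Full parameterization of the synthetic cohort."""

    n_participants: int = 10_000
    deletion_prevalence: float = 0.0038
    cvm_prevalence: float = 0.0059
    neuropsych_prevalence: float = 0.0072
    or_cvm: float = 1.73
    or_neuropsych: float = 1.84
    decoy_rates: dict = field(default_factory=_default_decoy_rates)
    cognitive_effects: dict = field(default_factory=_default_cognitive_effects)
    qualification_probs: dict = field(default_factory=_default_qualification_probs)
    fecundity_rates: dict = field(default_factory=_default_fecundity_rates)
    qc_fail_rates: dict = field(default_factory=_default_qc_fail_rates)
    deletion_boundary_jitter_bp: int = 2_000
    noise_code_rate: float = 0.05  # benign non-classifying code per participant
    background_cnv_mean: float = 6.0  # genome-wide calls per clean sample
    locus: GenomicInterval = BP1_BP2_LOCUS
    min_fraction: float = 0.95
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        for name in ("deletion_prevalence", "cvm_prevalence",
                     "neuropsych_prevalence", "noise_code_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for name in ("or_cvm", "or_neuropsych"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for kind, rate in self.decoy_rates.items():
            if kind not in DECOY_KINDS:
                raise ConfigurationError(f"decoy_rates: unknown decoy kind {kind!r}")
            if not 0 <= rate <= 1:
                raise ConfigurationError(f"decoy_rates[{kind!r}] must be in [0, 1]")
        cvm_decoy_total = sum(
            r for k, r in self.decoy_rates.items() if k != "neuropsych_other_f"
        )
        if cvm_decoy_total > 1:
            raise ConfigurationError("decoy_rates: CVM decoy rates sum to > 1")
        for group, probs in self.qualification_probs.items():
            if len(probs) != 3 or any(p < 0 for p in probs):
                raise ConfigurationError(
                    f"qualification_probs[{group!r}] needs 3 non-negative entries"
                )
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"qualification_probs[{group!r}] must sum to 1"
                )
        for sex, rates in self.fecundity_rates.items():
            for grp, r in rates.items():
                if r <= 0:
                    raise ConfigurationError(
                        f"fecundity_rates[{sex!r}][{grp!r}] must be > 0"
                    )
        for name, rate in self.qc_fail_rates.items():
            if not 0 <= rate <= 1:
                raise ConfigurationError(f"qc_fail_rates[{name!r}] must be in [0, 1]")
        if self.deletion_boundary_jitter_bp < 0:
            raise ConfigurationError("deletion_boundary_jitter_bp must be >= 0")
        slack = self.locus.length * (1 - self.min_fraction)
        if 2 * self.deletion_boundary_jitter_bp > slack:
            raise ConfigurationError(
                "deletion_boundary_jitter_bp too large: worst-case inward jitter "
                f"({2 * self.deletion_boundary_jitter_bp} bp) would push a "
                f"designated carrier below the {self.min_fraction:.0%} overlap rule "
                f"(slack {slack:.0f} bp)"
            )
        if self.background_cnv_mean < 0:
            raise ConfigurationError("background_cnv_mean must be >= 0")


class SimulatedCohort(NamedTuple):
    participants: pd.DataFrame
    events: pd.DataFrame
    cnv_calls: pd.DataFrame
    sample_stats: pd.DataFrame
    outcomes: pd.DataFrame
    ground_truth: pd.DataFrame


def solve_noncarrier_risk(prevalence: float, carrier_frac: float, odds_ratio: float) -> float:
    """Non-carrier risk p0 such that the population OR equals ``odds_ratio``.

    Solves q*p1 + (1-q)*p0 = prevalence with odds(p1) = OR * odds(p0) by
    1-D root finding.
    """
    if prevalence <= 0:
        return 0.0

    def f(p0: float) -> float:
        odds1 = odds_ratio * p0 / (1 - p0)
        p1 = odds1 / (1 + odds1)
        return carrier_frac * p1 + (1 - carrier_frac) * p0 - prevalence

    return float(brentq(f, 1e-12, 1 - 1e-12))


def _carrier_risk(p0: float, odds_ratio: float) -> float:
    if p0 == 0:
        return 0.0
    odds1 = odds_ratio * p0 / (1 - p0)
    return odds1 / (1 + odds1)


# ---------------------------------------------------------------------------
# event-history emission


def _uniform_age(rng, lo: float, hi: float) -> int:
    hi = max(lo + 1, hi)
    return int(rng.integers(int(lo), int(hi) + 1))


def emit_code_history(truth, codebook: Codebook, rng) -> list[dict]:
    """Emit the clinical events realizing one participant's ground truth.

    ``truth`` is a mapping with participant_id, year_of_birth, deceased,
    true_cvm (case / control / decoy kind), true_neuropsych (case / control /
    neuropsych_other_f). True CVM cases receive one sampled case-defining
    code path; each decoy kind receives exactly the code pattern the
    classifier must route to EXCLUDED; controls receive no classifying
    codes. Event ages are consistent with year of birth. Deceased
    participants realizing an ICD-coded path may carry it as a
    cause-of-death (DEATH system) record instead of a hospital code.

    Returns event rows as dicts (participant_id, system, code,
    age_at_event, tiebreak).
    """
    pid = truth["participant_id"]
    yob = int(truth["year_of_birth"])
    max_age = max(2015 - yob, 20)
    events: list[dict] = []

    def add(system: str, code: str, age: float, tiebreak: float = 0.0) -> None:
        events.append(
            {
                "participant_id": pid,
                "system": system,
                "code": code,
                "age_at_event": age,
                "tiebreak": tiebreak,
            }
        )

    cvm = truth["true_cvm"]
    if cvm == "case":
        path = int(rng.integers(0, 6))
        if path == 0:  # congenital circulatory ICD diagnosis
            code = str(rng.choice(["Q250", "Q203", "Q231", "Q212"]))
            system = "ICD10"
            if truth.get("deceased") and rng.random() < 0.5:
                system = "DEATH"
            add(system, code, _uniform_age(rng, 0, max_age))
        elif path == 1:  # atrial septal defect via Q21.1 alone
            add("ICD10", "Q211", _uniform_age(rng, 20, max_age))
        elif path == 2:  # congenital-heart operation code
            add("OPCS4", "K041", _uniform_age(rng, 0, max_age))
        elif path == 3:  # self-reported congenital heart disease
            add("SELF_ILLNESS", "1588", _uniform_age(rng, 40, max_age))
        elif path == 4:  # self-reported heart surgery in childhood
            add("SELF_OPERATION", "1553", _uniform_age(rng, 0, 17))
        else:  # aortic valve disease diagnosed before 65 (BAV pattern)
            add("ICD10", "I350", _uniform_age(rng, 30, min(64, max_age)))
    elif cvm == "pfo_k165":
        age = _uniform_age(rng, 30, max_age)
        add("ICD10", "Q211", age)
        add("OPCS4", "K165", age, tiebreak=0.5)
    elif cvm == "pfo_prior_stroke":
        age = _uniform_age(rng, 40, max(41, max_age - 2))
        add("ICD10", "I639", age)
        add("ICD10", "Q211", age + 2)
    elif cvm == "bav_age_ge_65":
        add("ICD10", "I350", _uniform_age(rng, 65, max(66, max_age)))
    elif cvm == "bav_endocarditis":
        age = _uniform_age(rng, 30, min(64, max_age))
        add("ICD10", "I350", age)
        add("ICD10", "I330", age, tiebreak=0.5)
    elif cvm == "syndrome":
        add("ICD10", "Q900", _uniform_age(rng, 0, 40))
    elif cvm != "control":
        raise ConfigurationError(f"unknown true_cvm kind {cvm!r}")

    np_status = truth["true_neuropsych"]
    if np_status == "case":
        code = str(rng.choice(["F200", "F310", "F840", "F810", "F700"]))
        add("ICD10", code, _uniform_age(rng, 18, max_age))
    elif np_status == "neuropsych_other_f":
        add("ICD10", "F410", _uniform_age(rng, 20, max_age))
    elif np_status != "control":
        raise ConfigurationError(f"unknown true_neuropsych kind {np_status!r}")

    return events


# ---------------------------------------------------------------------------
# CNV calls


def simulate_cnv_calls(truth, params: CohortParams, rng) -> tuple[list[dict], dict]:
    """Simulate one sample's CNV calls and QC stats from its ground truth.

    Carriers receive a single copy-number-1 segment covering the locus with
    boundary jitter small enough to satisfy the overlap rule (validated in
    :meth:`CohortParams.validate`); no sample is ever assigned copy number 0
    at the locus. Background autosomal calls are placed off chromosome 15;
    samples designated QC failures get >40 calls or out-of-range waviness.
    """
    params.validate()
    pid = truth["participant_id"]
    calls: list[dict] = []

    fail_wav = bool(truth.get("qc_fail_waviness", False))
    fail_count = bool(truth.get("qc_fail_count", False))

    n_background = (
        41 + int(rng.poisson(5))
        if fail_count
        else int(rng.poisson(params.background_cnv_mean))
    )
    chroms = [str(c) for c in range(1, 23) if c != 15]
    for _ in range(n_background):
        start = int(rng.integers(1_000_000, 100_000_000))
        length = int(rng.integers(1_000, 200_000))
        calls.append(
            {
                "sample_id": pid,
                "chromosome": str(rng.choice(chroms)),
                "start": start,
                "end": start + length,
                "copy_number": int(rng.choice([1, 3])),
                "n_probes": int(rng.integers(3, 80)),
            }
        )

    if truth["carrier"]:
        j = params.deletion_boundary_jitter_bp
        start = params.locus.start + int(rng.integers(-j, j + 1)) if j else params.locus.start
        end = params.locus.end + int(rng.integers(-j, j + 1)) if j else params.locus.end
        calls.append(
            {
                "sample_id": pid,
                "chromosome": params.locus.chromosome,
                "start": start,
                "end": end,
                "copy_number": 1,
                "n_probes": int(rng.integers(40, 120)),
            }
        )

    if fail_wav:
        wf = float(rng.uniform(0.031, 0.08)) * (1 if rng.random() < 0.5 else -1)
    else:
        wf = float(rng.uniform(-0.029, 0.029))
    stats = {"sample_id": pid, "waviness_factor": wf, "n_cnvs": len(calls)}
    return calls, stats


# ---------------------------------------------------------------------------
# full cohort


def simulate_cohort(params: CohortParams) -> SimulatedCohort:
    """Generate a complete synthetic cohort. Deterministic given params.seed."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_participants
    ids = np.array([f"S{i:07d}" for i in range(n)])

    sex = np.where(rng.random(n) < 0.54, "female", "male")
    yob = rng.integers(1938, 1971, size=n)
    deceased = rng.random(n) < 0.03
    carrier = rng.random(n) < params.deletion_prevalence

    # OR-targeted phenotype risks
    true_cvm = _assign_phenotype(
        rng,
        carrier,
        params.cvm_prevalence,
        params.deletion_prevalence,
        params.or_cvm,
    )
    true_np = _assign_phenotype(
        rng,
        carrier,
        params.neuropsych_prevalence,
        params.deletion_prevalence,
        params.or_neuropsych,
    )

    # CVM decoys among non-cases, mutually exclusive kinds
    cvm_kinds = [k for k in DECOY_KINDS if k != "neuropsych_other_f"]
    u = rng.random(n)
    cvm_label = np.where(true_cvm, "case", "control").astype(object)
    lo = 0.0
    for kind in cvm_kinds:
        rate = params.decoy_rates.get(kind, 0.0)
        mask = (~true_cvm) & (u >= lo) & (u < lo + rate)
        cvm_label[mask] = kind
        lo += rate
    # the >=65 decoy needs an attained age of at least 65
    old_enough = np.asarray(cvm_label == "bav_age_ge_65")
    if old_enough.any():
        yob = yob.copy()
        yob[old_enough] = rng.integers(1938, 1949, size=int(old_enough.sum()))

    np_label = np.where(true_np, "case", "control").astype(object)
    rate = params.decoy_rates.get("neuropsych_other_f", 0.0)
    mask = (~true_np) & (rng.random(n) < rate)
    np_label[mask] = "neuropsych_other_f"

    fail_wav = rng.random(n) < params.qc_fail_rates.get("waviness", 0.0)
    fail_count = rng.random(n) < params.qc_fail_rates.get("excess_cnvs", 0.0)
    qc_pass = ~(fail_wav | fail_count)

    participants = pd.DataFrame(
        {
            "participant_id": ids,
            "sex": sex,
            "year_of_birth": yob,
            "deceased": deceased,
        }
    )
    ground_truth = pd.DataFrame(
        {
            "participant_id": ids,
            "carrier": carrier,
            "true_cvm": cvm_label,
            "true_neuropsych": np_label,
            "qc_pass": qc_pass,
        }
    )

    events = _emit_all_events(params, rng, ids, yob, deceased, cvm_label, np_label)
    cnv_calls, sample_stats = _emit_all_cnvs(
        params, rng, ids, carrier, fail_wav, fail_count
    )
    outcomes = _emit_outcomes(params, rng, ids, sex, yob, carrier)
    return SimulatedCohort(
        participants, events, cnv_calls, sample_stats, outcomes, ground_truth
    )


def _assign_phenotype(rng, carrier, prevalence, carrier_frac, odds_ratio):
    p0 = solve_noncarrier_risk(prevalence, carrier_frac, odds_ratio)
    p1 = _carrier_risk(p0, odds_ratio)
    risk = np.where(carrier, p1, p0)
    return rng.random(len(carrier)) < risk


def _emit_all_events(params, rng, ids, yob, deceased, cvm_label, np_label):
    codebook = Codebook.default()
    needs = (cvm_label != "control") | (np_label != "control")
    rows: list[dict] = []
    for i in np.flatnonzero(needs):
        truth = {
            "participant_id": ids[i],
            "year_of_birth": int(yob[i]),
            "deceased": bool(deceased[i]),
            "true_cvm": cvm_label[i],
            "true_neuropsych": np_label[i],
            "carrier": False,  # not used by the emitter
        }
        rows.extend(emit_code_history(truth, codebook, rng))

    # benign non-classifying noise codes (asthma) on a random subset
    noisy = np.flatnonzero(rng.random(len(ids)) < params.noise_code_rate)
    if len(noisy):
        ages = rng.integers(10, 60, size=len(noisy))
        rows.extend(
            {
                "participant_id": ids[i],
                "system": "ICD10",
                "code": "J459",
                "age_at_event": int(a),
                "tiebreak": 0.0,
            }
            for i, a in zip(noisy, ages)
        )
    events = pd.DataFrame(
        rows,
        columns=["participant_id", "system", "code", "age_at_event", "tiebreak"],
    )
    return events.sort_values(
        ["participant_id", "age_at_event", "tiebreak"], kind="stable"
    ).reset_index(drop=True)


def _emit_all_cnvs(params, rng, ids, carrier, fail_wav, fail_count):
    n = len(ids)
    counts = rng.poisson(params.background_cnv_mean, size=n)
    n_excess = int(fail_count.sum())
    if n_excess:
        counts = counts.copy()
        counts[fail_count] = 41 + rng.poisson(5, size=n_excess)

    total = int(counts.sum())
    chrom_pool = np.array([str(c) for c in range(1, 23) if c != 15], dtype=object)
    bg = pd.DataFrame(
        {
            "sample_id": np.repeat(ids, counts),
            "chromosome": rng.choice(chrom_pool, size=total),
            "start": rng.integers(1_000_000, 100_000_000, size=total),
            "copy_number": rng.choice([1, 3], size=total),
            "n_probes": rng.integers(3, 80, size=total),
        }
    )
    bg["end"] = bg["start"] + rng.integers(1_000, 200_000, size=total)

    n_carriers = int(carrier.sum())
    j = params.deletion_boundary_jitter_bp
    if j:
        start_jit = rng.integers(-j, j + 1, size=n_carriers)
        end_jit = rng.integers(-j, j + 1, size=n_carriers)
    else:
        start_jit = end_jit = np.zeros(n_carriers, dtype=int)
    locus_calls = pd.DataFrame(
        {
            "sample_id": ids[carrier],
            "chromosome": params.locus.chromosome,
            "start": params.locus.start + start_jit,
            "copy_number": 1,
            "n_probes": rng.integers(40, 120, size=n_carriers),
            "end": params.locus.end + end_jit,
        }
    )
    cols = ["sample_id", "chromosome", "start", "end", "copy_number", "n_probes"]
    calls = pd.concat([bg[cols], locus_calls[cols]], ignore_index=True)
    calls = calls.sort_values(["sample_id", "chromosome", "start"], kind="stable")
    calls = calls.reset_index(drop=True)

    wf = rng.uniform(-0.029, 0.029, size=n)
    n_wav = int(fail_wav.sum())
    if n_wav:
        sign = np.where(rng.random(n_wav) < 0.5, -1.0, 1.0)
        wf[fail_wav] = sign * rng.uniform(0.031, 0.08, size=n_wav)
    n_cnvs = counts + carrier.astype(int)
    stats = pd.DataFrame(
        {"sample_id": ids, "waviness_factor": wf, "n_cnvs": n_cnvs}
    )
    return calls, stats


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def _emit_outcomes(params, rng, ids, sex, yob, carrier):
    n = len(ids)
    eff = params.cognitive_effects
    age = 2009 - yob  # age at the assessment visit
    carrier_f = carrier.astype(float)

    reaction_time = rng.normal(
        REACTION_TIME_MEAN + eff["reaction_time_shift"] * carrier_f,
        REACTION_TIME_SD,
    )
    fluid = rng.poisson(
        np.exp(np.log(FLUID_INTELLIGENCE_RATE) + eff["fluid_intelligence_log_rate"] * carrier_f)
    )
    nm_hi = rng.random(n) < _expit(
        NUMERIC_MEMORY_BASE_LOGIT + eff["numeric_memory_log_odds"] * carrier_f
    )
    numeric_memory = np.where(nm_hi, 7 + rng.binomial(2, 0.3, size=n), rng.integers(3, 7, size=n))
    pm_any = rng.random(n) < _expit(
        PAIRS_MATCHING_BASE_LOGIT + eff["pairs_matching_log_odds"] * carrier_f
    )
    pairs = np.where(pm_any, 1 + rng.poisson(0.7, size=n), 0)

    quals = np.empty(n, dtype=object)
    categories = np.array(["other", "degree", "a_levels"], dtype=object)
    for grp, mask in (("carrier", carrier), ("non_carrier", ~carrier)):
        k = int(mask.sum())
        if k:
            quals[mask] = rng.choice(
                categories, size=k, p=params.qualification_probs[grp]
            )

    fec = np.empty(n, dtype=int)
    for s in ("male", "female"):
        for grp, cmask in (("carrier", carrier), ("non_carrier", ~carrier)):
            mask = (sex == s) & cmask
            k = int(mask.sum())
            if k:
                fec[mask] = rng.poisson(params.fecundity_rates[s][grp], size=k)

    return pd.DataFrame(
        {
            "participant_id": ids,
            "age": age,
            "sex": sex,
            "reaction_time": reaction_time,
            "fluid_intelligence": fluid,
            "numeric_memory": numeric_memory,
            "pairs_matching": pairs,
            "qualifications": quals,
            "fecundity": fec,
        }
    )
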