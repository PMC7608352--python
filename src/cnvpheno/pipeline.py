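"""End-to-end orchestration: simulate/load -> QC -> genotype -> phenotype ->
associate, with a reproducible JSON/Markdown report.

Stages are plain functions over DataFrames so each is independently
runnable; :func:`run_pipeline` wires them together from a
:class:`RunConfig`. Every count in the report is reconstructible from the
intermediate tables the pipeline emits.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cnv import (
    BP1_BP2_LOCUS,
    CNVCall,
    GenomicInterval,
    detect_locus_deletion,
)
from .codebook import Codebook
from .phenotype import (
    CASE,
    CONTROL,
    EXCLUDED,
    ClinicalEvent,
    classify_cvm,
    classify_neuropsych,
    cognitive_eligibility,
)
from .simulate import CohortParams, ConfigurationError, simulate_cohort
from .stats import (
    OUTCOME_SPECS,
    ContingencyTable,
    FitFailure,
    attainment_proportions,
    fecundity_analysis,
    fit_adjusted_model,
    or_ci_chi2,
)
from . import io as cio

__all__ = [
    "RunConfig",
    "run_pipeline",
    "emit_report",
    "genotype_cohort",
    "phenotype_cohort",
    "association_tables",
    "regression_battery",
]

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Exactly one of ``simulate`` (generator parameters) or ``inputs``
    (a map of file paths: participants, events, cnv_calls, sample_stats,
    outcomes, optional ground_truth) must be given.
    """

    simulate: CohortParams | None = None
    inputs: dict | None = None
    codebook_path: str | None = None
    locus: GenomicInterval = BP1_BP2_LOCUS
    min_fraction: float = 0.95
    wf_limit: float = 0.03
    max_cnvs: int = 40
    out_dir: str | None = None
    seed: int = 0
    report_formats: tuple[str, ...] = ("json", "md")

    def validate(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ConfigurationError(
                "exactly one of 'simulate' or 'inputs' must be configured"
            )
        if self.inputs is not None:
            required = {"participants", "events", "cnv_calls", "sample_stats",
                        "outcomes"}
            missing = required - set(self.inputs)
            if missing:
                raise ConfigurationError(f"inputs missing entries: {sorted(missing)}")
            for name, path in self.inputs.items():
                if path is not None and not Path(path).exists():
                    raise ConfigurationError(f"inputs[{name!r}]: no such file {path}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        cfg = cls()
        if "simulate" in raw and raw["simulate"] is not None:
            sim = dict(raw["simulate"])
            try:
                cfg.simulate = CohortParams(**sim)
            except TypeError as exc:
                raise ConfigurationError(f"simulate block: {exc}") from exc
        if "inputs" in raw and raw["inputs"] is not None:
            cfg.inputs = dict(raw["inputs"])
        if "locus" in raw and raw["locus"]:
            chrom, _, span = str(raw["locus"]).partition(":")
            start, _, end = span.partition("-")
            cfg.locus = GenomicInterval(chrom, int(start.replace(",", "")),
                                        int(end.replace(",", "")))
        for key in ("codebook_path", "out_dir"):
            if raw.get(key):
                setattr(cfg, key, str(raw[key]))
        for key in ("min_fraction", "wf_limit"):
            if key in raw:
                setattr(cfg, key, float(raw[key]))
        for key in ("max_cnvs", "seed"):
            if key in raw:
                setattr(cfg, key, int(raw[key]))
        if "report_formats" in raw:
            cfg.report_formats = tuple(raw["report_formats"])
        return cfg

    def to_dict(self) -> dict:
        d = {
            "simulate": dataclasses.asdict(self.simulate) if self.simulate else None,
            "inputs": {k: str(v) for k, v in self.inputs.items()}
            if self.inputs
            else None,
            "codebook_path": self.codebook_path,
            "locus": f"{self.locus.chromosome}:{self.locus.start}-{self.locus.end}",
            "min_fraction": self.min_fraction,
            "wf_limit": self.wf_limit,
            "max_cnvs": self.max_cnvs,
            "out_dir": self.out_dir,
            "seed": self.seed,
            "report_formats": list(self.report_formats),
        }
        if d["simulate"] is not None:
            d["simulate"]["locus"] = (
                f"{self.simulate.locus.chromosome}:"
                f"{self.simulate.locus.start}-{self.simulate.locus.end}"
            )
        return d


# ---------------------------------------------------------------------------
# stages


def genotype_cohort(
    calls: pd.DataFrame,
    sample_stats: pd.DataFrame,
    locus: GenomicInterval = BP1_BP2_LOCUS,
    min_fraction: float = 0.95,
    wf_limit: float = 0.03,
    max_cnvs: int = 40,
) -> pd.DataFrame:
    """Per-sample QC plus locus-deletion genotype for every sample.

    Returns one row per sample in ``sample_stats`` with columns sample_id,
    qc_pass, qc_reason, carrier, overlap_fraction, anomaly. QC failures
    (waviness strictly outside +/-wf_limit, or strictly more than max_cnvs
    calls) are still genotyped but flagged.
    """
    wf = sample_stats["waviness_factor"].to_numpy(dtype=float)
    n_cnvs = sample_stats["n_cnvs"].to_numpy()
    fail_wav = np.abs(wf) > wf_limit
    fail_count = (~fail_wav) & (n_cnvs > max_cnvs)
    qc_reason = np.where(fail_wav, "waviness", np.where(fail_count, "cnv_count", ""))

    chrom = calls["chromosome"].astype(str)
    at_locus = calls[
        (chrom == locus.chromosome)
        & (calls["start"] <= locus.end)
        & (calls["end"] >= locus.start)
        & (calls["copy_number"] < 2)
    ]
    status: dict[str, tuple[bool, float, str]] = {}
    for sid, grp in at_locus.groupby("sample_id", sort=False):
        sample_calls = [
            CNVCall(str(sid), str(r.chromosome), int(r.start), int(r.end),
                    int(r.copy_number))
            for r in grp.itertuples(index=False)
        ]
        ds = detect_locus_deletion(sample_calls, locus, min_fraction)
        status[str(sid)] = (ds.carrier, ds.overlap_fraction, ds.anomaly or "")

    sids = sample_stats["sample_id"].astype(str)
    carrier = sids.map(lambda s: status.get(s, (False, 0.0, ""))[0]).to_numpy()
    frac = sids.map(lambda s: status.get(s, (False, 0.0, ""))[1]).to_numpy()
    anomaly = sids.map(lambda s: status.get(s, (False, 0.0, ""))[2]).to_numpy()
    return pd.DataFrame(
        {
            "sample_id": sids.to_numpy(),
            "qc_pass": ~(fail_wav | fail_count),
            "qc_reason": qc_reason,
            "carrier": carrier,
            "overlap_fraction": frac,
            "anomaly": anomaly,
        }
    )


def phenotype_cohort(
    participants: pd.DataFrame,
    events: pd.DataFrame,
    codebook: Codebook,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every participant's CVM and neuropsychiatric status.

    Returns (assignments, cognitive) where assignments is long-format
    (participant_id, phenotype, status, reason) and cognitive has
    participant_id, eligible. Participants with no events are controls and
    cognitively eligible by construction.
    """
    grouped: dict[str, list[ClinicalEvent]] = {}
    for row in events.itertuples(index=False):
        ev = ClinicalEvent(
            str(row.participant_id),
            str(row.system),
            str(row.code),
            float(row.age_at_event),
            float(row.tiebreak),
        )
        grouped.setdefault(ev.participant_id, []).append(ev)

    pids = participants["participant_id"].astype(str).tolist()
    rows = []
    elig_rows = []
    no_events: list[ClinicalEvent] = []
    for pid in pids:
        evs = grouped.get(pid, no_events)
        if evs:
            cvm = classify_cvm(pid, evs, codebook)
            npsy = classify_neuropsych(pid, evs, codebook)
            eligible = cognitive_eligibility(pid, evs, codebook)
            rows.append((pid, cvm.phenotype, cvm.status, cvm.reason))
            rows.append((pid, npsy.phenotype, npsy.status, npsy.reason))
        else:
            rows.append((pid, "CVM", CONTROL, ""))
            rows.append((pid, "NEUROPSYCH", CONTROL, ""))
            eligible = True
        elig_rows.append((pid, eligible))

    assignments = pd.DataFrame(
        rows, columns=["participant_id", "phenotype", "status", "reason"]
    )
    cognitive = pd.DataFrame(elig_rows, columns=["participant_id", "eligible"])
    return assignments, cognitive


def association_tables(
    assignments: pd.DataFrame, genotypes: pd.DataFrame
) -> dict[str, dict]:
    """Carrier-by-phenotype 2x2 analysis for each phenotype.

    Only QC-passing samples enter the tables; EXCLUDED participants appear
    in neither margin.
    """
    geno = genotypes[genotypes["qc_pass"]][["sample_id", "carrier"]].rename(
        columns={"sample_id": "participant_id"}
    )
    out: dict[str, dict] = {}
    for phenotype, sub in assignments.groupby("phenotype"):
        merged = sub.merge(geno, on="participant_id", how="inner")
        cases = merged[merged["status"] == CASE]
        controls = merged[merged["status"] == CONTROL]
        a = int(cases["carrier"].sum())
        b = int(len(cases) - a)
        c = int(controls["carrier"].sum())
        d = int(len(controls) - c)
        table = ContingencyTable(a, b, c, d)
        entry: dict = {"table": {"a": a, "b": b, "c": c, "d": d}}
        try:
            res = or_ci_chi2(table)
            entry.update(
                odds_ratio=res.odds_ratio,
                ci_low=res.ci_low,
                ci_high=res.ci_high,
                chi2=res.chi2,
                p=res.p,
                prevalence_cases_pct=res.prevalence_cases,
                prevalence_controls_pct=res.prevalence_controls,
                haldane_corrected=res.haldane_corrected,
            )
        except ValueError as exc:
            entry["error"] = str(exc)
        out[phenotype] = entry
    return out


def _regression_entry(res) -> dict:
    entry = {
        "family": res.family,
        "n_used": res.n_used,
        "n_removed_as_outliers": res.n_removed_as_outliers,
        "terms": {
            name: {"coef": t.coef, "se": t.se, "p": t.p}
            for name, t in res.terms.items()
        },
    }
    if res.category_odds:
        entry["category_odds"] = {
            cat: {
                "coef": t.coef,
                "odds_ratio": float(np.exp(t.coef)),
                "se": t.se,
                "p": t.p,
            }
            for cat, t in res.category_odds.items()
        }
    return entry


def regression_battery(
    outcomes: pd.DataFrame,
    genotypes: pd.DataFrame,
    cognitive: pd.DataFrame,
) -> dict:
    """Adjusted models for cognition, qualifications and fecundity.

    Cognitive and qualification models run on QC-passing, cognitively
    eligible participants; fecundity runs per sex with an interaction test.
    """
    geno = genotypes[genotypes["qc_pass"]][["sample_id", "carrier"]].rename(
        columns={"sample_id": "participant_id"}
    )
    data = outcomes.merge(geno, on="participant_id", how="inner").merge(
        cognitive, on="participant_id", how="left"
    )
    data["eligible"] = data["eligible"].fillna(True)
    eligible = data[data["eligible"]]

    report: dict = {"n_eligible": int(len(eligible)),
                    "n_removed_cognitive_exclusions": int((~data["eligible"]).sum()),
                    "models": {}}
    for name in ("reaction_time", "fluid_intelligence", "numeric_memory",
                 "pairs_matching", "qualifications"):
        spec = OUTCOME_SPECS[name]
        try:
            res = fit_adjusted_model(spec, eligible)
            report["models"][name] = _regression_entry(res)
        except FitFailure as exc:
            report["models"][name] = {"family": spec.family, "error": str(exc)}

    male, female, inter_p = fecundity_analysis(eligible)
    report["fecundity"] = {
        "male": _regression_entry(male) if male else None,
        "female": _regression_entry(female) if female else None,
        "interaction_p": inter_p,
    }

    freq = (
        eligible.groupby(["qualifications", "carrier"]).size().unstack(fill_value=0)
    )
    freq.columns = ["carrier" if c else "non_carrier" for c in freq.columns]
    pct = attainment_proportions(freq)
    report["attainment"] = {
        "counts": {col: freq[col].to_dict() for col in freq.columns},
        "percentages": {col: pct[col].to_dict() for col in pct.columns},
    }
    return report


# ---------------------------------------------------------------------------
# orchestration


def _status_counts(assignments: pd.DataFrame, phenotype: str) -> dict:
    sub = assignments[assignments["phenotype"] == phenotype]
    counts = sub["status"].value_counts().to_dict()
    reasons = (
        sub[sub["status"] == EXCLUDED]["reason"].value_counts().to_dict()
    )
    return {"status": {k: int(v) for k, v in counts.items()},
            "excluded_reasons": {k: int(v) for k, v in reasons.items()}}


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages and return the report dict (also written to disk when
    ``config.out_dir`` is set). Identical config and seed give an identical
    report."""
    config.validate()

    if config.simulate is not None:
        cohort = simulate_cohort(config.simulate)
        data = cohort._asdict()
    else:
        data = cio.read_cohort_inputs(config.inputs)

    codebook = (
        Codebook.from_yaml(config.codebook_path)
        if config.codebook_path
        else Codebook.default()
    )

    genotypes = genotype_cohort(
        data["cnv_calls"], data["sample_stats"], config.locus,
        config.min_fraction, config.wf_limit, config.max_cnvs,
    )
    assignments, cognitive = phenotype_cohort(
        data["participants"], data["events"], codebook
    )
    associations = association_tables(assignments, genotypes)
    regressions = regression_battery(data["outcomes"], genotypes, cognitive)

    cfg_dict = config.to_dict()
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True).encode()
    ).hexdigest()[:16]
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "config_hash": cfg_hash,
        "counts": {
            "samples": int(len(data["sample_stats"])),
            "cnv_calls": int(len(data["cnv_calls"])),
            "qc_failed": {
                k: int(v)
                for k, v in genotypes[~genotypes["qc_pass"]]["qc_reason"]
                .value_counts()
                .items()
            },
            "carriers_qc_pass": int(
                genotypes[genotypes["qc_pass"]]["carrier"].sum()
            ),
            "cvm": _status_counts(assignments, "CVM"),
            "neuropsych": _status_counts(assignments, "NEUROPSYCH"),
        },
        "associations": associations,
        "regressions": regressions,
    }

    if config.out_dir:
        outdir = Path(config.out_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        cio.write_tsv(genotypes, outdir / "genotypes.tsv")
        cio.write_tsv(assignments, outdir / "assignments.tsv")
        cio.write_tsv(cognitive, outdir / "cognitive_eligibility.tsv")
        with open(outdir / "config.json", "w") as fh:
            json.dump(cfg_dict, fh, indent=2, sort_keys=True)
        emit_report(report, outdir, config.report_formats)
    return report


def emit_report(report: dict, outdir, formats=("json", "md")) -> list[Path]:
    """Write the report as machine JSON and/or human Markdown."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    if "json" in formats:
        path = outdir / "report.json"
        with open(path, "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        written.append(path)
    if "md" in formats:
        path = outdir / "report.md"
        path.write_text(_markdown_report(report))
        written.append(path)
    return written


def _fmt(x, nd=2):
    return "-" if x is None else f"{x:.{nd}f}"


def _markdown_report(report: dict) -> str:
    lines = ["# Deletion association report", ""]
    lines.append(f"seed: {report.get('seed')}  config: {report.get('config_hash')}")
    lines.append("")
    assoc = report.get("associations", {})
    if assoc:
        lines += [
            "## Deletion prevalence (2x2)",
            "",
            "| Phenotype | Carriers/cases | Carriers/controls | Prevalence cases | "
            "Prevalence controls | OR | 95% CI | p (Yates) |",
            "|---|---|---|---|---|---|---|---|",
        ]
        for pheno, e in sorted(assoc.items()):
            t = e["table"]
            if "error" in e:
                lines.append(f"| {pheno} | {t['a']}/{t['a']+t['b']} | "
                             f"{t['c']}/{t['c']+t['d']} | - | - | - | - | - |")
                continue
            lines.append(
                f"| {pheno} | {t['a']}/{t['a']+t['b']} | {t['c']}/{t['c']+t['d']} | "
                f"{_fmt(e['prevalence_cases_pct'])}% | "
                f"{_fmt(e['prevalence_controls_pct'])}% | "
                f"{_fmt(e['odds_ratio'])} | "
                f"[{_fmt(e['ci_low'])}, {_fmt(e['ci_high'])}] | "
                f"{e['p']:.3g} |"
            )
        lines.append("")
    reg = report.get("regressions", {})
    models = reg.get("models", {})
    if models:
        lines += [
            "## Adjusted regression battery",
            "",
            "| Outcome | Family | n | Deletion coef | SE | p |",
            "|---|---|---|---|---|---|",
        ]
        for name, e in sorted(models.items()):
            if "error" in e:
                lines.append(f"| {name} | {e['family']} | - | fit failed | - | - |")
                continue
            t = e["terms"].get("deletion")
            lines.append(
                f"| {name} | {e['family']} | {e['n_used']} | "
                f"{_fmt(t['coef'], 4)} | {_fmt(t['se'], 4)} | {t['p']:.3g} |"
            )
        lines.append("")
    fec = reg.get("fecundity")
    if fec:
        lines.append("## Fecundity (sex-stratified Poisson)")
        lines.append("")
        for sex in ("male", "female"):
            e = fec.get(sex)
            if e and "terms" in e:
                t = e["terms"]["deletion"]
                lines.append(
                    f"- {sex}: deletion coef {_fmt(t['coef'], 4)} "
                    f"(SE {_fmt(t['se'], 4)}, p {t['p']:.3g}, n {e['n_used']})"
                )
        ip = fec.get("interaction_p")
        lines.append(f"- deletion x sex interaction p: "
                     f"{'-' if ip is None else f'{ip:.3g}'}")
        lines.append("")
    att = reg.get("attainment")
    if att:
        lines += ["## Highest qualification attained (%)", ""]
        groups = sorted(att["percentages"])
        cats = sorted(
            {c for grp in att["percentages"].values() for c in grp}
        )
        lines.append("| Category | " + " | ".join(groups) + " |")
        lines.append("|---|" + "---|" * len(groups))
        for cat in cats:
            row = " | ".join(
                _fmt(att["percentages"][grp].get(cat), 1) for grp in groups
            )
            lines.append(f"| {cat} | {row} |")
        lines.append("")
    return "\n".join(lines)
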