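"""Readers and writers for the pipeline's tabular file formats.

All tabular files are tab-separated with a header row. CNV calls travel as
PennCNV-style rawcnv text (whitespace-separated, 1-based inclusive
coordinates) or as a TSV dialect with columns
sample_id/chromosome/start/end/copy_number[/n_probes]. The synthetic
generator writes exactly the formats the pipeline reads, so generator
output is pipeline input with no adapters.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .cnv import CNVCall, parse_cnv_calls

__all__ = [
    "read_tsv",
    "write_tsv",
    "read_cnv_calls",
    "write_rawcnv",
    "calls_to_frame",
    "write_cohort",
    "read_cohort_inputs",
]

EVENT_COLUMNS = ["participant_id", "system", "code", "age_at_event", "tiebreak"]


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"participant_id": str, "sample_id": str,
                                              "code": str}, **kwargs)


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def calls_to_frame(calls: list[CNVCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "chromosome": [c.chromosome for c in calls],
            "start": [c.start for c in calls],
            "end": [c.end for c in calls],
            "copy_number": [c.copy_number for c in calls],
            "n_probes": [c.n_probes for c in calls],
        }
    )


def read_cnv_calls(path, dialect: str | None = None) -> pd.DataFrame:
    """Read CNV calls from rawcnv or TSV; dialect inferred from suffix."""
    path = Path(path)
    if dialect is None:
        dialect = "tsv" if path.suffix == ".tsv" else "penncnv_rawcnv"
    with open(path) as fh:
        return calls_to_frame(parse_cnv_calls(fh, dialect=dialect))


def write_rawcnv(calls: pd.DataFrame, path) -> None:
    """Write calls as PennCNV-style rawcnv text."""
    with open(path, "w") as fh:
        for row in calls.itertuples(index=False):
            chrom = str(row.chromosome)
            if not chrom.startswith("chr"):
                chrom = f"chr{chrom}"
            length = int(row.end) - int(row.start) + 1
            n_probes = getattr(row, "n_probes", None)
            numsnp = int(n_probes) if pd.notna(n_probes) else 10
            cn = int(row.copy_number)
            state = cn + 1 if cn < 2 else cn  # PennCNV state index convention
            fh.write(
                f"{chrom}:{int(row.start)}-{int(row.end)}\t"
                f"numsnp={numsnp}\tlength={length:,}\t"
                f"state{state},cn={cn}\t{row.sample_id}\t"
                f"startsnp=rs0\tendsnp=rs0\n"
            )


COHORT_FILES = {
    "participants": "participants.tsv",
    "events": "events.tsv",
    "cnv_calls": "calls.rawcnv",
    "sample_stats": "sample_stats.tsv",
    "outcomes": "outcomes.tsv",
    "ground_truth": "ground_truth.tsv",
}


def write_cohort(cohort, outdir) -> dict[str, Path]:
    """Write a SimulatedCohort to a directory; returns the file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, fname in COHORT_FILES.items():
        path = outdir / fname
        df = getattr(cohort, name)
        if name == "cnv_calls":
            write_rawcnv(df, path)
        else:
            write_tsv(df, path)
        paths[name] = path
    return paths


def read_cohort_inputs(paths: dict) -> dict[str, pd.DataFrame]:
    """Read pipeline inputs from a {name: path} map (ground_truth optional)."""
    out = {}
    for name in ("participants", "events", "sample_stats", "outcomes", "ground_truth"):
        if name in paths and paths[name] is not None:
            out[name] = read_tsv(paths[name])
    out["cnv_calls"] = read_cnv_calls(paths["cnv_calls"])
    return out
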