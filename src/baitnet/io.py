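"""Readers and writers for every external table the pipeline touches.

All tables are tab-separated UTF-8 with a single header line, matching the
SAINTexpress / contaminant-repository export ecosystem. Gene identifiers
are opaque, case-sensitive strings; no symbol mapping is attempted.
Every reader/writer pair round-trips valid data exactly.
"""
from __future__ import annotations

import csv
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .types import (
    ComplexDefinition,
    ControlRun,
    CrapomeEntry,
    FormatError,
    GeneSet,
    PurificationRun,
    ScoredInteraction,
    ValidationError,
)

INTERACTION_COLUMNS = ["bait", "prey", "method", "avg_spec", "score"]

RUN_COLUMNS = ["bait", "method", "bio_rep", "tech_rep", "prey", "spectral_count"]
CONTROL_COLUMNS = ["control", "control_type", "method", "prey", "spectral_count"]


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return df


def read_runs(path: str | Path) -> list[PurificationRun]:
    """Read bait purification runs from a long-format TSV.

    One row per (bait, method, bio_rep, tech_rep, prey); counts for a prey
    repeated within the same run are summed.
    """
    df = _read_tsv(path, RUN_COLUMNS)
    grouped: dict[tuple[str, str, int, int], dict[str, int]] = defaultdict(dict)
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            count = int(row.spectral_count)
            bio = int(row.bio_rep)
            tech = int(row.tech_rep)
        except ValueError as exc:
            raise FormatError(f"{path}: non-integer field at row {i}: {exc}") from exc
        if count < 0:
            raise ValidationError(f"{path}: negative spectral count at row {i}")
        key = (row.bait, row.method, bio, tech)
        grouped[key][row.prey] = grouped[key].get(row.prey, 0) + count
    return [
        PurificationRun(bait_id=b, method=m, bio_replicate=br, tech_replicate=tr,
                        counts=counts)
        for (b, m, br, tr), counts in grouped.items()
    ]


def write_runs(runs: Iterable[PurificationRun], path: str | Path) -> None:
    rows = []
    for run in sorted(runs, key=lambda r: r.key):
        for prey in sorted(run.counts):
            rows.append((run.bait_id, run.method, run.bio_replicate,
                         run.tech_replicate, prey, run.counts[prey]))
    _write_rows(path, RUN_COLUMNS, rows)


def read_controls(path: str | Path) -> list[ControlRun]:
    """Read negative-control runs (same long format, keyed by control id)."""
    df = _read_tsv(path, CONTROL_COLUMNS)
    grouped: dict[tuple[str, str, str], dict[str, int]] = defaultdict(dict)
    for i, row in enumerate(df.itertuples(index=False), start=2):
        count = int(row.spectral_count)
        if count < 0:
            raise ValidationError(f"{path}: negative spectral count at row {i}")
        key = (row.control, row.control_type, row.method)
        grouped[key][row.prey] = grouped[key].get(row.prey, 0) + count
    return [
        ControlRun(control_id=c, control_type=t, method=m, counts=counts)
        for (c, t, m), counts in grouped.items()
    ]


def write_controls(controls: Iterable[ControlRun], path: str | Path) -> None:
    rows = []
    for run in sorted(controls, key=lambda r: (r.control_id, r.method)):
        for prey in sorted(run.counts):
            rows.append((run.control_id, run.control_type, run.method, prey,
                         run.counts[prey]))
    _write_rows(path, CONTROL_COLUMNS, rows)


def read_saint_output(path: str | Path, method: str | None = None) -> list[ScoredInteraction]:
    """Parse a SAINTexpress-style "list" output table.

    Requires columns Bait, Prey, AvgSpec, SaintScore. The method label is
    taken from a Method column if present, otherwise from the ``method``
    argument.
    """
    df = _read_tsv(path, ["Bait", "Prey", "AvgSpec", "SaintScore"])
    has_method = "Method" in df.columns
    if not has_method and method is None:
        raise FormatError(
            f"{path}: no Method column; pass method='BioID' or 'AP-MS'"
        )
    out: list[ScoredInteraction] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        pair = (row.Bait, row.Prey)
        if pair in seen:
            raise ValidationError(
                f"{path}: duplicate (bait, prey) pair {pair} at row {i}"
            )
        seen.add(pair)
        score = float(row.SaintScore)
        if not 0.0 <= score <= 1.0:
            raise ValidationError(
                f"{path}: SaintScore {score} outside [0, 1] at row {i}"
            )
        out.append(ScoredInteraction(
            bait_id=row.Bait,
            prey_id=row.Prey,
            method=row.Method if has_method else method,  # type: ignore[arg-type]
            avg_spectral_count=float(row.AvgSpec),
            saint_score=score,
        ))
    return out


def write_saint_output(interactions: Iterable[ScoredInteraction],
                       path: str | Path) -> None:
    rows = []
    for si in sorted(interactions, key=lambda s: (s.bait_id, s.prey_id)):
        rows.append((si.bait_id, si.prey_id, si.method,
                     _fmt(si.avg_spectral_count), _fmt(si.saint_score)))
    _write_rows(path, ["Bait", "Prey", "Method", "AvgSpec", "SaintScore"], rows)


def read_crapome(path: str | Path) -> dict[str, CrapomeEntry]:
    """Read a contaminant-repository profile table into a prey -> entry map.

    Preys absent from the table are treated downstream as frequency 0:
    absence from a contaminant repository is evidence of non-contamination.
    """
    df = _read_tsv(path, ["prey", "n_detected", "n_experiments",
                          "avg_spectral_count"])
    out: dict[str, CrapomeEntry] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        entry = CrapomeEntry(
            prey_id=row.prey,
            n_detected=int(row.n_detected),
            n_experiments=int(row.n_experiments),
            avg_spectral_count=float(row.avg_spectral_count),
        )
        out[entry.prey_id] = entry
    return out


def write_crapome(entries: Iterable[CrapomeEntry], path: str | Path) -> None:
    rows = [(e.prey_id, e.n_detected, e.n_experiments, _fmt(e.avg_spectral_count))
            for e in sorted(entries, key=lambda e: e.prey_id)]
    _write_rows(path, ["prey", "n_detected", "n_experiments",
                       "avg_spectral_count"], rows)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from the standard GMT format (term, description, genes...)."""
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: GMT line {lineno} has {len(fields)} fields (< 3)"
                )
            sets.append(GeneSet(
                term_id=fields[0],
                term_name=fields[1],
                members=frozenset(g for g in fields[2:] if g),
            ))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for gs in sets:
            fh.write("\t".join([gs.term_id, gs.term_name, *sorted(gs.members)]))
            fh.write("\n")


def normalize_pair(a: str, b: str) -> tuple[str, str]:
    """Canonical undirected gene pair: lexicographically sorted tuple."""
    return (a, b) if a <= b else (b, a)


def read_edge_list(path: str | Path) -> set[tuple[str, str]]:
    """Read a two-column edge list into a set of normalized undirected pairs."""
    df = _read_tsv(path, [])
    if df.shape[1] < 2:
        raise FormatError(f"{path}: edge list needs at least two columns")
    pairs = set()
    for row in df.itertuples(index=False):
        pairs.add(normalize_pair(str(row[0]), str(row[1])))
    return pairs


def write_edge_list(pairs: Iterable[tuple[str, str]], path: str | Path) -> None:
    rows = sorted(normalize_pair(a, b) for a, b in pairs)
    _write_rows(path, ["gene_a", "gene_b"], rows)


def read_localization(path: str | Path) -> dict[str, set[str]]:
    """Read a prey -> compartments map (one row per prey, compartment)."""
    df = _read_tsv(path, ["prey", "compartment"])
    out: dict[str, set[str]] = defaultdict(set)
    for row in df.itertuples(index=False):
        out[row.prey].add(row.compartment)
    return dict(out)


def read_complexes(path: str | Path) -> list[ComplexDefinition]:
    """Read complex definitions (one row per complex_name, subunit)."""
    df = _read_tsv(path, ["complex_name", "subunit"])
    grouped: dict[str, set[str]] = defaultdict(set)
    for row in df.itertuples(index=False):
        grouped[row.complex_name].add(row.subunit)
    return [ComplexDefinition(complex_name=name, subunits=frozenset(subs))
            for name, subs in sorted(grouped.items())]


def read_interaction_table(path: str | Path) -> pd.DataFrame:
    """Read a distilled interaction table into a typed DataFrame."""
    df = _read_tsv(path, INTERACTION_COLUMNS)
    df = df.astype({"avg_spec": float, "score": float})
    validate_interaction_table(df)
    return df


def write_interaction_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_interaction_table(table)
    out = table.copy()
    out["avg_spec"] = out["avg_spec"].map(_fmt)
    out["score"] = out["score"].map(_fmt)
    out.to_csv(path, sep="\t", index=False)


def validate_interaction_table(table: pd.DataFrame) -> None:
    for col in INTERACTION_COLUMNS:
        if col not in table.columns:
            raise FormatError(f"interaction table missing column {col!r}")
    dup = table.duplicated(subset=["bait", "prey", "method"])
    if dup.any():
        row = table[dup].iloc[0]
        raise ValidationError(
            f"duplicate interaction row ({row['bait']}, {row['prey']}, "
            f"{row['method']})"
        )


def _fmt(x: float) -> str:
    """Render a float without trailing-zero noise (bit-stable round trips)."""
    return repr(float(x))


def _write_rows(path: str | Path, header: Sequence[str],
                rows: Iterable[Sequence]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        writer.writerows(rows)
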