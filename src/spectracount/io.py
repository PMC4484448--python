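"""Readers and writers for the pipeline's interchange formats.

Formats: PSM TSV (one row per peptide-spectrum match), protein-group TSV,
differential TSV, GMT annotation sets, two-column TSV / SIF edge lists,
and JSON summaries. Writers use fixed numeric formatting (RSc to 4
decimals, p/q in scientific notation) so that repeated runs with the same
inputs produce byte-identical tables, and every writer's output is parsed
losslessly by its paired reader. Accessions are opaque case-sensitive
strings throughout.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .enrich import AnnotationSet, EnrichmentRecord
from .identify import PSM_COLUMNS, ProteinGroup
from .quantify import DifferentialRecord


class SchemaError(ValueError):
    """A table is missing required columns or contains malformed rows."""


# ---------------------------------------------------------------- PSM tables

def read_psm_table(path: str | Path) -> pd.DataFrame:
    """Read a PSM TSV, validating schema and per-row values.

    Required columns (any order): spectrum_id, peptide, protein, score,
    identity_threshold, is_decoy, sample. Malformed rows (non-finite score
    or threshold, empty peptide, is_decoy not 0/1) are reported with their
    1-based data row numbers.
    """
    frame = pd.read_csv(path, sep="\t", dtype={"spectrum_id": str})
    missing = [c for c in PSM_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing PSM column(s): {', '.join(missing)}"
        )
    frame = frame[list(PSM_COLUMNS)]
    bad_rows: list[int] = []
    score = pd.to_numeric(frame["score"], errors="coerce")
    thresh = pd.to_numeric(frame["identity_threshold"], errors="coerce")
    decoy = pd.to_numeric(frame["is_decoy"], errors="coerce")
    bad = (
        ~np.isfinite(score)
        | ~np.isfinite(thresh)
        | ~decoy.isin([0, 1])
        | frame["peptide"].astype(str).str.len().eq(0)
    )
    bad_rows = (np.flatnonzero(bad.to_numpy()) + 1).tolist()
    if bad_rows:
        shown = ", ".join(map(str, bad_rows[:10]))
        raise SchemaError(f"{path}: malformed PSM row(s) at {shown}")
    frame["score"] = score.astype(float)
    frame["identity_threshold"] = thresh.astype(float)
    frame["is_decoy"] = decoy.astype(bool)
    frame["sample"] = frame["sample"].astype(str)
    frame["protein"] = frame["protein"].astype(str)
    frame["peptide"] = frame["peptide"].astype(str)
    return frame


def write_psm_table(psms: pd.DataFrame, path: str | Path) -> None:
    out = psms[list(PSM_COLUMNS)].copy()
    out["is_decoy"] = out["is_decoy"].astype(int)
    out["score"] = out["score"].map(lambda v: f"{v:.4f}")
    out["identity_threshold"] = out["identity_threshold"].map(lambda v: f"{v:.4f}")
    out.to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------ protein groups

def write_protein_groups(
    groups: list[ProteinGroup], path: str | Path, samples: list[str] | None = None
) -> None:
    """Protein-group TSV: protein, n_unique_peptides, one count column per
    sample, is_decoy, and the peptide set (semicolon-joined) for round-trips."""
    if samples is None:
        seen: list[str] = []
        for g in groups:
            for s in g.spectra:
                if s not in seen:
                    seen.append(s)
        samples = sorted(seen)
    rows = [
        {
            "protein": g.protein,
            "n_unique_peptides": len(g.unique_peptides),
            **{f"spectra_{s}": int(g.spectra.get(s, 0)) for s in samples},
            "is_decoy": int(g.is_decoy),
            "peptides": ";".join(sorted(g.unique_peptides)),
        }
        for g in groups
    ]
    columns = (
        ["protein", "n_unique_peptides"]
        + [f"spectra_{s}" for s in samples]
        + ["is_decoy", "peptides"]
    )
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def read_protein_groups(path: str | Path) -> list[ProteinGroup]:
    frame = pd.read_csv(path, sep="\t")
    required = {"protein", "n_unique_peptides", "is_decoy", "peptides"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s): {', '.join(sorted(missing))}")
    count_cols = [c for c in frame.columns if c.startswith("spectra_")]
    groups = []
    for row in frame.to_dict("records"):
        spectra = {c[len("spectra_"):]: int(row[c]) for c in count_cols}
        raw = row["peptides"]
        peptides = (
            frozenset(str(raw).split(";")) if isinstance(raw, str) and raw
            else frozenset()
        )
        groups.append(
            ProteinGroup(
                protein=str(row["protein"]),
                unique_peptides=peptides,
                spectra=spectra,
                is_decoy=bool(row["is_decoy"]),
            )
        )
    return groups


# ---------------------------------------------------------- differential TSV

def write_differential_table(
    records: list[DifferentialRecord], path: str | Path
) -> None:
    rows = [
        {
            "protein": r.protein,
            "s_a": r.s_a,
            "s_b": r.s_b,
            "t_a": r.t_a,
            "t_b": r.t_b,
            "rsc_signed": f"{r.rsc_signed:.4f}",
            "partition": r.partition,
            "high_tier": int(r.high_tier),
        }
        for r in records
    ]
    columns = ["protein", "s_a", "s_b", "t_a", "t_b", "rsc_signed",
               "partition", "high_tier"]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def read_differential_table(path: str | Path) -> list[DifferentialRecord]:
    frame = pd.read_csv(path, sep="\t")
    return [
        DifferentialRecord(
            protein=str(r.protein),
            s_a=int(r.s_a),
            s_b=int(r.s_b),
            t_a=int(r.t_a),
            t_b=int(r.t_b),
            rsc_signed=float(r.rsc_signed),
            partition=str(r.partition),
            high_tier=bool(r.high_tier),
        )
        for r in frame.itertuples(index=False)
    ]


# ------------------------------------------------------------------ GMT sets

def read_gmt(path: str | Path, vocabulary: str | None = None) -> AnnotationSet:
    """Standard GMT: category <tab> description <tab> member1 <tab> member2..."""
    categories: dict[str, frozenset[str]] = {}
    path = Path(path)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise SchemaError(
                f"{path}:{lineno}: GMT line needs category, description and "
                f"at least one member"
            )
        name = parts[0]
        if name in categories:
            raise SchemaError(f"{path}:{lineno}: duplicate category {name!r}")
        members = frozenset(m for m in parts[2:] if m)
        if not members:
            raise SchemaError(f"{path}:{lineno}: category {name!r} has no members")
        categories[name] = members
    return AnnotationSet(vocabulary=vocabulary or path.stem, categories=categories)


def write_gmt(categories: dict[str, frozenset[str]], path: str | Path) -> None:
    lines = [
        "\t".join([name, "na", *sorted(members)])
        for name, members in sorted(categories.items())
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------- edge lists

def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Two-column TSV of undirected interactions; errors carry line numbers."""
    edges = []
    path = Path(path)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2 or not parts[0] or not parts[1]:
            raise SchemaError(
                f"{path}:{lineno}: expected two tab-separated accessions"
            )
        edges.append((parts[0], parts[1]))
    return edges


def write_edge_list(edges: list[tuple[str, str]], path: str | Path) -> None:
    lines = [f"{a}\t{b}" for a, b in edges]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_sif(path: str | Path) -> list[tuple[str, str]]:
    """SIF lines: source <relation> target [target2 ...]."""
    edges = []
    path = Path(path)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 3:
            raise SchemaError(
                f"{path}:{lineno}: SIF line needs source, relation, target"
            )
        source = parts[0]
        edges.extend((source, target) for target in parts[2:])
    return edges


def write_sif(
    edges: list[tuple[str, str]], path: str | Path, relation: str = "pp"
) -> None:
    lines = [f"{a}\t{relation}\t{b}" for a, b in edges]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ------------------------------------------------------------- enrichment TSV

def write_enrichment_table(
    records: list[EnrichmentRecord], path: str | Path
) -> None:
    rows = [
        {
            "category": r.category,
            "k": r.k,
            "n": r.n,
            "K": r.K,
            "N": r.N,
            "fold": f"{r.fold:.4f}",
            "p_value": f"{r.p_value:.6e}",
            "q_value": f"{r.q_value:.6e}",
            "direction": r.direction,
        }
        for r in records
    ]
    columns = ["category", "k", "n", "K", "N", "fold", "p_value", "q_value",
               "direction"]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


# -------------------------------------------------------------- JSON helpers

def write_json_summary(payload: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_truth_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    required = {"protein", "baseline", "fold", "module", "contaminant"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s): {', '.join(sorted(missing))}")
    return frame
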