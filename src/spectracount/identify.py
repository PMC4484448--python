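"""Peptide-spectrum-match filtering, protein inference and target-decoy FDR.

The identification stage mirrors common shotgun-proteomics practice for
gel-band LC-MS/MS searches: a PSM is *significant* when its search-engine
ion score strictly exceeds its own per-spectrum identity threshold, a
protein is reported only when supported by at least two distinct peptide
sequences, and the false-discovery rate is estimated from decoy-database
hits that survive the same filters.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

#: Canonical column order of a PSM table (one row per peptide-spectrum match).
PSM_COLUMNS = (
    "spectrum_id",
    "peptide",
    "protein",
    "score",
    "identity_threshold",
    "is_decoy",
    "sample",
)

_MOD_PATTERN = re.compile(r"\([^)]*\)|\[[^\]]*\]")


def strip_modifications(peptide: str) -> str:
    """Reduce a peptide string to its bare upper-case sequence.

    Bracketed modification annotations — Mascot-style ``M(Oxidation)`` or
    delta-mass style ``M[+16]`` — are removed before sequences are compared,
    so that modified and unmodified forms of one peptide count as a single
    unique sequence.
    """
    return _MOD_PATTERN.sub("", peptide).upper()


@dataclass(frozen=True)
class ProteinGroup:
    """A protein inferred from significant PSMs.

    ``spectra`` maps sample label -> number of significant spectra assigned
    to the protein in that sample (the ``s`` of the RSc formula).
    """

    protein: str
    unique_peptides: frozenset[str]
    spectra: dict[str, int] = field(hash=False)
    is_decoy: bool = False

    @property
    def total_spectra(self) -> int:
        return int(sum(self.spectra.values()))


@dataclass(frozen=True)
class IdentificationSummary:
    n_target_proteins: int
    n_decoy_proteins: int
    fdr: float


def filter_significant_psms(psms: pd.DataFrame) -> pd.DataFrame:
    """Keep PSMs whose score is strictly greater than their identity threshold.

    Row order is preserved and the input frame is not modified; a score
    exactly equal to the threshold is *not* significant.
    """
    _require_columns(psms, ("score", "identity_threshold"))
    mask = psms["score"] > psms["identity_threshold"]
    return psms.loc[mask].copy()


def infer_proteins(
    psms: pd.DataFrame, min_unique_peptides: int = 2
) -> list[ProteinGroup]:
    """Collapse significant PSMs to proteins under a unique-peptide cut-off.

    PSMs are grouped by accession; distinct peptide *sequences* (compared
    case-insensitively after stripping modification notation) are counted,
    and groups with fewer than ``min_unique_peptides`` distinct sequences
    are discarded. Per-sample spectra counts are tallied over all
    significant PSMs of the retained groups. A peptide matching several
    accessions counts toward each of them; no razor/parsimony assignment
    is attempted.

    Parameters
    ----------
    psms:
        Score-filtered PSM table (see :func:`filter_significant_psms`).
    min_unique_peptides:
        Minimum number of distinct peptide sequences per protein
        (default 2, the standard two-unique-peptide rule).
    """
    if min_unique_peptides < 1:
        raise ValueError(
            f"min_unique_peptides must be >= 1, got {min_unique_peptides}"
        )
    _require_columns(psms, PSM_COLUMNS)
    if psms.empty:
        return []

    work = psms[["protein", "peptide", "is_decoy", "sample"]].copy()
    work["peptide"] = work["peptide"].map(strip_modifications)

    groups: list[ProteinGroup] = []
    for protein, sub in work.groupby("protein", sort=True):
        peptides = frozenset(sub["peptide"])
        if len(peptides) < min_unique_peptides:
            continue
        spectra = sub.groupby("sample", sort=True).size().to_dict()
        spectra = {str(k): int(v) for k, v in spectra.items()}
        is_decoy = bool(sub["is_decoy"].iloc[0])
        groups.append(
            ProteinGroup(
                protein=str(protein),
                unique_peptides=peptides,
                spectra=spectra,
                is_decoy=is_decoy,
            )
        )
    return groups


def estimate_fdr(
    groups: list[ProteinGroup], mode: str = "decoy_over_target"
) -> IdentificationSummary:
    """Protein-level target-decoy FDR over inferred groups.

    ``mode='decoy_over_target'`` (default) estimates FDR as D/T, the decoy
    count over the target count. ``mode='combined'`` uses 2D/(T+D), the
    concatenated-database estimator. Zero decoys give FDR 0; zero targets
    are an error because the estimate is undefined.
    """
    n_decoy = sum(1 for g in groups if g.is_decoy)
    n_target = len(groups) - n_decoy
    if n_target == 0:
        raise ValueError("FDR is undefined: no target proteins in input")
    if mode == "decoy_over_target":
        fdr = n_decoy / n_target
    elif mode == "combined":
        fdr = 2 * n_decoy / (n_target + n_decoy)
    else:
        raise ValueError(f"unknown FDR mode: {mode!r}")
    return IdentificationSummary(
        n_target_proteins=n_target, n_decoy_proteins=n_decoy, fdr=fdr
    )


def _require_columns(frame: pd.DataFrame, columns) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ValueError(f"PSM table is missing column(s): {', '.join(missing)}")
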