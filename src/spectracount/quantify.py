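"""Signed RSc quantitation and differential partitioning of two secretomes.

The ratio of normalized spectral counts (RSc) compares per-protein
significant-spectra counts between a *test* and a *reference* sample::

    r = (s_test + c) * (T_ref - s_ref + c) / ((s_ref + c) * (T_test - s_test + c))

where ``s`` is the protein's significant-spectra count, ``T`` the sample's
total significant spectra and ``c`` a pseudo-count correction factor
(default 1.25). Ratios below 1 are reported as their negative inverse, so
the signed statistic never falls in the open interval (-1, 1): +2 means
two-fold higher in the test sample, -2 two-fold higher in the reference.
The pseudo-count keeps the ratio finite for proteins detected in only one
sample, which is how fold changes are quoted for secretome-exclusive
proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter

from .identify import ProteinGroup

PARTITIONS = (
    "unique_A",
    "unique_B",
    "common_higher_B",
    "common_lower_B",
    "common_unchanged",
)


@dataclass(frozen=True)
class QuantConfig:
    """Thresholds of the differential analysis.

    c:
        RSc pseudo-count correction factor (> 0).
    fold_cutoff:
        Inclusive signed-RSc magnitude for the higher/lower-abundance call
        ("at least two-fold").
    high_tier_cutoff:
        Strict cutoff for the extreme tier ("more than 15-fold").
    """

    c: float = 1.25
    fold_cutoff: float = 2.0
    high_tier_cutoff: float = 15.0

    def __post_init__(self) -> None:
        if not self.c > 0:
            raise ValueError(f"c must be > 0, got {self.c}")
        if self.fold_cutoff < 1:
            raise ValueError(f"fold_cutoff must be >= 1, got {self.fold_cutoff}")
        if self.high_tier_cutoff < self.fold_cutoff:
            raise ValueError("high_tier_cutoff must be >= fold_cutoff")


@dataclass(frozen=True)
class DifferentialRecord:
    protein: str
    s_a: int
    s_b: int
    t_a: int
    t_b: int
    rsc_signed: float
    partition: str
    high_tier: bool


def compute_rsc(
    s_test: int, s_ref: int, T_test: int, T_ref: int, c: float = 1.25
) -> float:
    """Signed RSc of one protein, oriented so positive means test-enriched.

    Returns the raw ratio ``r`` when ``r >= 1`` and ``-1/r`` otherwise.
    """
    if c <= 0:
        raise ValueError(f"correction factor c must be > 0, got {c}")
    for name, s, T in (("test", s_test, T_test), ("ref", s_ref, T_ref)):
        if s < 0 or T < 0:
            raise ValueError(f"negative count in {name} sample")
        if s > T:
            raise ValueError(
                f"{name} sample: spectra count {s} exceeds sample total {T}"
            )
    r = ((s_test + c) * (T_ref - s_ref + c)) / ((s_ref + c) * (T_test - s_test + c))
    return r if r >= 1.0 else -1.0 / r


def quantify_pair(
    groups_a: list[ProteinGroup],
    groups_b: list[ProteinGroup],
    config: QuantConfig | None = None,
) -> list[DifferentialRecord]:
    """Differential records for the union of target proteins of two samples.

    ``groups_a``/``groups_b`` are the per-sample inference results; decoy
    groups are excluded, and sample totals T_A, T_B are sums of significant
    spectra over the retained target proteins of each sample. Sample B is
    the test sample: positive signed RSc means higher abundance in B.

    Partition labels: a protein counted in exactly one sample is
    ``unique_A``/``unique_B``; common proteins are ``common_higher_B`` when
    the signed RSc is >= +fold_cutoff (inclusive), ``common_lower_B`` when
    <= -fold_cutoff, otherwise ``common_unchanged``. ``high_tier`` flags
    records with signed RSc strictly above high_tier_cutoff.
    """
    config = config or QuantConfig()
    counts_a = _target_counts(groups_a)
    counts_b = _target_counts(groups_b)
    t_a = sum(counts_a.values())
    t_b = sum(counts_b.values())
    union = sorted(set(counts_a) | set(counts_b))
    if union and (t_a == 0 or t_b == 0):
        raise ValueError("zero total significant spectra in one sample")

    records = []
    for protein in union:
        s_a = counts_a.get(protein, 0)
        s_b = counts_b.get(protein, 0)
        rsc = compute_rsc(s_b, s_a, t_b, t_a, c=config.c)
        if s_a > 0 and s_b == 0:
            partition = "unique_A"
        elif s_b > 0 and s_a == 0:
            partition = "unique_B"
        elif rsc >= config.fold_cutoff:
            partition = "common_higher_B"
        elif rsc <= -config.fold_cutoff:
            partition = "common_lower_B"
        else:
            partition = "common_unchanged"
        records.append(
            DifferentialRecord(
                protein=protein,
                s_a=s_a,
                s_b=s_b,
                t_a=t_a,
                t_b=t_b,
                rsc_signed=rsc,
                partition=partition,
                high_tier=rsc > config.high_tier_cutoff,
            )
        )
    return records


def summarize_partition(records: list[DifferentialRecord]) -> dict[str, int]:
    """Partition sizes, union total, and the combined increase count.

    ``n_increase_B`` counts proteins with at least a fold_cutoff increase in
    sample B: the unique-to-B set plus the common higher-abundance set.
    """
    counts = Counter(r.partition for r in records)
    summary = {p: int(counts.get(p, 0)) for p in PARTITIONS}
    summary["total"] = len(records)
    summary["n_increase_B"] = summary["unique_B"] + summary["common_higher_B"]
    summary["n_high_tier"] = sum(1 for r in records if r.high_tier)
    return summary


def tier_counts(
    rsc_values, config: QuantConfig | None = None
) -> dict[str, int]:
    """Tier membership counts for a list of signed RSc / fold values.

    ``n_at_least_fold_cutoff`` uses the inclusive comparison of the
    higher-abundance call ("at least two-fold"); ``n_above_high_tier``
    is strict ("more than 15-fold").
    """
    config = config or QuantConfig()
    values = list(rsc_values)
    return {
        "n_at_least_fold_cutoff": sum(1 for v in values if v >= config.fold_cutoff),
        "n_above_high_tier": sum(1 for v in values if v > config.high_tier_cutoff),
    }


def _target_counts(groups: list[ProteinGroup]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for g in groups:
        if g.is_decoy:
            continue
        n = g.total_spectra
        if n > 0:
            counts[g.protein] = counts.get(g.protein, 0) + n
    return counts
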