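"""Ground-truthed simulator for two-condition spectral-counting secretomics.

The generator emulates the data-generating process a label-free secretome
comparison assumes: two conditioned-media samples ("SH-SY5Y-like" reference
A and "SK-N-BE2-like" test B) produce a fixed budget of significant-quality
MS/MS spectra per sample, allocated to proteins by multinomial sampling
with probability proportional to abundance — multiplied by a planted fold
change in the up-regulated sample. On top of this it plants the structures
the downstream stages must detect:

* a fraction of proteins with a signed fold change (>= +1 up in B,
  <= -1 up in A, 1 = null), drawn over a configurable magnitude range;
* a co-regulated protease-like module — proteins sharing one annotation
  category, strongly elevated in B, and densely wired in the interaction
  network (the cathepsin-module analogue);
* decoy PSMs whose scores sit stochastically below the identity-threshold
  distribution, so the realized protein-level false-discovery rate is small
  but tunable;
* an intracellular-leakage channel: a per-sample fraction of spectra is
  diverted to contamination-flagged proteins annotated as DNA/RNA binding,
  mimicking the slight differential cell death of the two cultures
  (defaults 8.5% vs 7.8%);
* a deliberate fraction of proteins carrying exactly one tryptic peptide,
  which the two-unique-peptide inference filter must remove.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sc_io

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of one synthetic secretome comparison.

    The defaults emulate the scale of a two-cell-line secretome catalogue:
    ~900 detectable proteins, a few thousand significant spectra per
    sample, a 20-member planted module, and leakage fractions mirroring
    the 8.5%/7.8% cell-death rates of the two cultures.
    """

    n_proteins: int = 900
    frac_differential: float = 0.3
    fold_range: tuple[float, float] = (2.0, 30.0)
    total_spectra_per_sample: int = 2000
    decoy_fraction: float = 0.05
    leakage_fraction_per_sample: tuple[float, float] = (0.085, 0.078)
    module_size: int = 20
    seed: int = 0

    # Secondary knobs (fixed study-design choices, rarely varied).
    sample_names: tuple[str, str] = ("SH-SY5Y-like", "SK-N-BE2-like")
    contaminant_fraction: float = 0.10
    single_peptide_fraction: float = 0.08
    mean_peptides_per_protein: float = 7.0
    peptide_length: int = 10
    identity_score: float = 40.0
    identity_jitter_sd: float = 2.0
    target_score_shift: float = 8.0
    target_score_sd: float = 4.0
    decoy_score_shift: float = -4.0
    decoy_score_sd: float = 3.0
    decoy_pool_fraction: float = 0.2
    module_fold_range: tuple[float, float] = (8.0, 30.0)
    module_density: float = 0.6
    background_mean_degree: float = 2.0
    n_generic_categories: int = 20
    abundance_sigma: float = 1.0
    module_category: str = "cysteine-type peptidase activity"

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be positive")
        for name in ("frac_differential", "decoy_fraction", "contaminant_fraction",
                     "single_peptide_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for v in self.leakage_fraction_per_sample:
            if not 0.0 <= v <= 1.0:
                raise ValueError("leakage fractions must be in [0, 1]")
        if self.fold_range[0] < 1 or self.fold_range[1] < self.fold_range[0]:
            raise ValueError("fold_range must satisfy 1 <= low <= high")
        if self.module_size > self.n_proteins:
            raise ValueError("module_size cannot exceed n_proteins")
        if self.module_size < 0:
            raise ValueError("module_size must be non-negative")
        if not 0.0 <= self.module_density <= 1.0:
            raise ValueError("module_density must be in [0, 1]")


@dataclass(frozen=True)
class SimulationTruth:
    """Planted ground truth for one simulated comparison.

    ``fold`` uses the signed convention of the quantitation stage: values
    >= +1 mean up-regulation in sample B, <= -1 up-regulation in sample A,
    and exactly 1 means no change.
    """

    proteins: tuple[str, ...]
    baseline: np.ndarray = field(hash=False)
    fold: np.ndarray = field(hash=False)
    module_member: np.ndarray = field(hash=False)
    contaminant: np.ndarray = field(hash=False)
    categories: dict[str, tuple[str, ...]] = field(hash=False)

    @property
    def n_differential(self) -> int:
        return int(np.sum(np.abs(self.fold) > 1))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein": self.proteins,
                "baseline": self.baseline,
                "fold": self.fold,
                "module": self.module_member.astype(int),
                "contaminant": self.contaminant.astype(int),
            }
        )


def generate_truth(config: SimulationConfig) -> SimulationTruth:
    """Plant abundances, fold changes, module membership and annotations.

    Exactly ``round(frac_differential * n_proteins)`` proteins receive a
    fold change of magnitude > 1. Module members are drawn from the
    up-in-B differential proteins and share one annotation category with
    elevated folds; contamination-flagged proteins are never differential
    and carry DNA-/RNA-binding annotations, since they enter the sample by
    leakage rather than secretion.
    """
    rng = np.random.default_rng([1, config.seed])
    n = config.n_proteins
    proteins = tuple(f"PROT{i:05d}" for i in range(n))
    baseline = rng.lognormal(mean=0.0, sigma=config.abundance_sigma, size=n)
    fold = np.ones(n)
    module_member = np.zeros(n, dtype=bool)
    contaminant = np.zeros(n, dtype=bool)

    n_cont = round(config.contaminant_fraction * n)
    n_diff = round(config.frac_differential * n)
    order = rng.permutation(n)
    cont_idx = order[:n_cont]
    secreted_idx = order[n_cont:]
    if n_diff > len(secreted_idx):
        raise ValueError(
            "frac_differential too large for the non-contaminant protein pool"
        )
    contaminant[cont_idx] = True
    diff_idx = secreted_idx[:n_diff]

    # Module members come first from the differential pool (forced up in B
    # with elevated folds); if the pool is smaller than the module, the
    # remainder are null proteins that merely share the module category so
    # the exact differential count is preserved.
    n_mod_diff = min(config.module_size, n_diff)
    module_idx = diff_idx[:n_mod_diff]
    if config.module_size > n_mod_diff:
        extra = [i for i in secreted_idx[n_diff:]][: config.module_size - n_mod_diff]
        module_idx = np.concatenate([module_idx, np.asarray(extra, dtype=int)])
    module_member[module_idx.astype(int)] = True

    lo, hi = config.module_fold_range
    fold[diff_idx[:n_mod_diff]] = rng.uniform(lo, hi, size=n_mod_diff)
    rest = diff_idx[n_mod_diff:]
    magnitudes = rng.uniform(config.fold_range[0], config.fold_range[1], len(rest))
    # keep magnitudes strictly above 1 so the differential count is exact
    magnitudes = np.maximum(magnitudes, np.nextafter(1.0, 2.0))
    signs = rng.choice([1.0, -1.0], size=len(rest))
    fold[rest] = np.where(signs > 0, magnitudes, -magnitudes)

    categories: dict[str, list[str]] = {p: [] for p in proteins}
    for j, i in enumerate(sorted(cont_idx.tolist())):
        categories[proteins[i]].append("DNA binding" if j % 2 == 0 else "RNA binding")
    for i in module_idx.tolist():
        categories[proteins[i]].append(config.module_category)
    if config.n_generic_categories > 0:
        generic = [f"category_{j:02d}" for j in range(config.n_generic_categories)]
        for i in secreted_idx.tolist():
            n_cat = rng.integers(1, 3)
            picks = rng.choice(config.n_generic_categories, size=n_cat, replace=False)
            categories[proteins[i]].extend(generic[j] for j in picks)

    return SimulationTruth(
        proteins=proteins,
        baseline=baseline,
        fold=fold,
        module_member=module_member,
        contaminant=contaminant,
        categories={p: tuple(c) for p, c in categories.items()},
    )


def simulate_psm_table(
    truth: SimulationTruth, config: SimulationConfig
) -> dict[str, pd.DataFrame]:
    """Draw one PSM table per sample from the planted truth.

    Per sample, ``total_spectra_per_sample`` target spectra are split into
    a secretion channel (multinomial over non-contaminant proteins, weights
    abundance x fold in the up-regulated sample) and a leakage channel
    (multinomial over contamination-flagged proteins, sized by the sample's
    leakage fraction). Decoy PSMs are added on top, sized by
    ``decoy_fraction`` of the target depth, with scores shifted below the
    identity-threshold distribution. Each PSM picks a peptide uniformly
    from its protein's tryptic inventory.
    """
    if config.total_spectra_per_sample <= 0:
        raise ValueError("total_spectra_per_sample must be positive")
    rng = np.random.default_rng([2, config.seed])
    n = len(truth.proteins)
    depth = config.total_spectra_per_sample

    inv_sizes = _peptide_inventory_sizes(rng, n, config)
    n_decoy_prot = (
        max(1, round(config.decoy_pool_fraction * n)) if config.decoy_fraction > 0 else 0
    )
    decoy_names = tuple(f"DECOY{i:05d}" for i in range(n_decoy_prot))
    decoy_inv_sizes = np.maximum(
        2, rng.poisson(max(config.mean_peptides_per_protein - 2.0, 0.0), n_decoy_prot) + 2
    ) if n_decoy_prot else np.zeros(0, dtype=int)

    all_sizes = np.concatenate([inv_sizes, decoy_inv_sizes]).astype(int)
    flat_peptides, offsets = _make_peptide_pool(rng, all_sizes, config.peptide_length)
    all_names = np.array(truth.proteins + decoy_names)

    sec = ~truth.contaminant
    tables = {}
    for s_idx, sample in enumerate(config.sample_names):
        up_b = truth.fold >= 1.0
        if s_idx == 1:  # test sample B
            weights = truth.baseline * np.where(up_b, truth.fold, 1.0)
        else:  # reference sample A; negative folds mean up in A
            weights = truth.baseline * np.where(up_b, 1.0, -truth.fold)

        leak = config.leakage_fraction_per_sample[s_idx]
        n_leak = round(leak * depth) if truth.contaminant.any() else 0
        n_sec = depth - n_leak

        counts = np.zeros(len(all_names), dtype=int)
        w_sec = weights * sec
        counts[: n][sec] += rng.multinomial(n_sec, w_sec[sec] / w_sec[sec].sum())
        if n_leak:
            w_leak = truth.baseline[truth.contaminant]
            counts[:n][truth.contaminant] += rng.multinomial(
                n_leak, w_leak / w_leak.sum()
            )
        n_decoy_psm = round(config.decoy_fraction * depth)
        if n_decoy_psm and n_decoy_prot:
            counts[n:] += rng.multinomial(
                n_decoy_psm, np.full(n_decoy_prot, 1.0 / n_decoy_prot)
            )

        prot_idx = np.repeat(np.arange(len(all_names)), counts)
        m = len(prot_idx)
        pep_pick = offsets[prot_idx] + rng.integers(0, all_sizes[prot_idx])
        identity = config.identity_score + rng.normal(0.0, config.identity_jitter_sd, m)
        is_decoy = prot_idx >= n
        shift = np.where(is_decoy, config.decoy_score_shift, config.target_score_shift)
        sd = np.where(is_decoy, config.decoy_score_sd, config.target_score_sd)
        scores = identity + rng.normal(0.0, 1.0, m) * sd + shift

        tables[sample] = pd.DataFrame(
            {
                "spectrum_id": [f"{sample}.{i:06d}" for i in range(m)],
                "peptide": flat_peptides[pep_pick],
                "protein": all_names[prot_idx],
                "score": np.round(scores, 4),
                "identity_threshold": np.round(identity, 4),
                "is_decoy": is_decoy,
                "sample": sample,
            }
        )
    return tables


def simulate_interaction_network(
    truth: SimulationTruth, config: SimulationConfig
) -> list[tuple[str, str]]:
    """Edge list with a densely wired planted module on a sparse background.

    The background is an Erdos-Renyi graph over all target proteins with
    expected degree ``background_mean_degree``; module members additionally
    receive an exact random subset of ``ceil(density * m(m-1)/2)`` internal
    edges, so the planted module's internal edge count is deterministic.
    """
    import networkx as nx

    rng = np.random.default_rng([3, config.seed])
    n = len(truth.proteins)
    p_bg = min(1.0, config.background_mean_degree / max(n - 1, 1))
    bg_seed = int(rng.integers(0, 2**31 - 1))
    bg = nx.fast_gnp_random_graph(n, p_bg, seed=bg_seed)
    edges = {tuple(sorted((truth.proteins[a], truth.proteins[b]))) for a, b in bg.edges()}

    members = [truth.proteins[i] for i in np.flatnonzero(truth.module_member)]
    pairs = [
        (members[i], members[j])
        for i in range(len(members))
        for j in range(i + 1, len(members))
    ]
    if pairs:
        n_internal = math.ceil(config.module_density * len(pairs))
        picks = rng.choice(len(pairs), size=n_internal, replace=False)
        edges.update(tuple(sorted(pairs[i])) for i in picks)
    return sorted(edges)


def write_fixture_bundle(
    truth: SimulationTruth,
    psms: dict[str, pd.DataFrame],
    path: str | Path,
    config: SimulationConfig | None = None,
) -> dict[str, Path]:
    """Write a complete analysis-ready fixture bundle to a directory.

    Emits one PSM TSV per sample, a GMT annotation file (one line per
    distinct category), a two-column interaction edge list, and a planted
    truth table for assertions. All files round-trip through the package
    readers; identical (truth, psms, config) produce byte-identical files.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    for sample, table in psms.items():
        safe = sample.replace("/", "_").replace(" ", "_")
        out = path / f"psms_{safe}.tsv"
        sc_io.write_psm_table(table, out)
        written[f"psms:{sample}"] = out

    cat_to_members: dict[str, list[str]] = {}
    for protein, cats in truth.categories.items():
        for cat in cats:
            cat_to_members.setdefault(cat, []).append(protein)
    gmt = path / "annotations.gmt"
    sc_io.write_gmt(
        {c: frozenset(m) for c, m in cat_to_members.items()}, gmt
    )
    written["gmt"] = gmt

    if config is not None:
        edges = simulate_interaction_network(truth, config)
    else:
        edges = []
    net = path / "interactions.tsv"
    sc_io.write_edge_list(edges, net)
    written["edges"] = net

    truth_path = path / "truth.tsv"
    truth.to_frame().to_csv(
        truth_path, sep="\t", index=False, float_format="%.6g"
    )
    written["truth"] = truth_path
    return written


def fdr_calibration_config(seed: int = 0) -> SimulationConfig:
    """Bundle configuration for quantitative FDR calibration studies.

    Uses a larger catalogue (2000 proteins, 40000 spectra/sample) so the
    realized decoy-protein count concentrates, with the decoy score shift
    set so that decoy proteins surviving the full identification filter
    make up ~0.5% of accepted proteins — i.e. a true contaminant rate of
    half the 1% FDR criterion the identification stage must meet.
    """
    return SimulationConfig(
        n_proteins=2000,
        total_spectra_per_sample=40000,
        decoy_fraction=0.1,
        decoy_score_shift=-6.4,
        seed=seed,
    )


def _peptide_inventory_sizes(
    rng: np.random.Generator, n: int, config: SimulationConfig
) -> np.ndarray:
    sizes = 2 + rng.poisson(max(config.mean_peptides_per_protein - 2.0, 0.0), n)
    n_single = round(config.single_peptide_fraction * n)
    single = rng.choice(n, size=n_single, replace=False)
    sizes[single] = 1
    return sizes.astype(int)


def _make_peptide_pool(
    rng: np.random.Generator, sizes: np.ndarray, length: int
) -> tuple[np.ndarray, np.ndarray]:
    """Flat array of random peptide strings plus per-protein offsets."""
    total = int(sizes.sum())
    letters = _AMINO_ACIDS[rng.integers(0, len(_AMINO_ACIDS), size=(total, length))]
    flat = np.array(["".join(row) for row in letters], dtype=object)
    offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]]).astype(int)
    return flat, offsets
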