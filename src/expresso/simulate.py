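"""Synthetic paired-species expression maps with planted orthology structure.

The generator emulates two bulk transcriptome atlases of species whose organs
do not match one-to-one. A latent "organ axis" in [0, 1] carries a pool of
expression archetypes — smooth positive intensity curves (mixtures of
Gaussian bumps). Each species samples the axis at its own set of sample-label
positions (different numbers of labels model unmatched morphologies), each
label carries independent biological replicates, and read counts are drawn
from a negative binomial around gene intensity x per-column library factor.

Planted structure:

* conserved orthopair — both genes draw intensity from the same archetype
  (similar profiles up to the species' different axis sampling);
* diverged orthopair — the two genes use independent archetypes but keep a
  correlated overall expression magnitude (orthologs tend to retain
  expression level even when the pattern diverges);
* coexpressed background pair — two non-orthologous genes that happen to
  share an archetype, the noise source that motivates iterated training;
* larger orthogroups (1x2, 1x3, 2x2) in which each co-ortholog independently
  retains the ancestral archetype with the conservation rate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
import numpy as np
import pandas as pd

from .baseline import SampleMatching
from .core import ExpressionMap, GenePair, OrthoGroup, PairSet
from .errors import ConfigurationError

__all__ = [
    "SimulationConfig",
    "SimulatedComparison",
    "simulate_species_pair",
    "simulate_self_comparison",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of a simulated two-species comparison.

    Defaults mirror a desk-scale version of a real plant atlas pair: a few
    thousand genes, 40 vs 30 sample labels (79 vs 54 columns with two
    replicates), negative-binomial overdispersion 0.1, 80% of orthopairs with
    conserved expression.
    """

    n_genes_a: int = 2000
    n_genes_b: int = 2000
    n_sample_labels_a: int = 40
    n_sample_labels_b: int = 30
    replicates_per_label: int = 2
    n_archetypes: int = 120
    conservation_rate: float = 0.8
    coexpressed_background_rate: float = 0.05
    dispersion: float = 0.1
    library_size: float = 1_000_000.0
    #: fraction of the smaller gene set placed into orthogroups
    orthogroup_gene_fraction: float = 0.8
    orthogroup_shape_mix: tuple[tuple[tuple[int, int], float], ...] = (
        ((1, 1), 0.70),
        ((1, 2), 0.15),
        ((1, 3), 0.10),
        ((2, 2), 0.05),
    )
    #: per-column library-factor log-sd (technical/batch variation)
    column_factor_sd: float = 0.1
    #: log-sd of the magnitude jitter between orthologous genes
    magnitude_jitter_sd: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes_a", "n_genes_b", "n_sample_labels_a",
                     "n_sample_labels_b", "replicates_per_label", "n_archetypes"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be a positive integer")
        for name in ("conservation_rate", "coexpressed_background_rate",
                     "orthogroup_gene_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be non-negative")
        if self.library_size <= 0:
            raise ConfigurationError("library_size must be positive")
        weights = [w for _, w in self.orthogroup_shape_mix]
        if any(w < 0 for w in weights) or not np.isclose(sum(weights), 1.0):
            raise ConfigurationError("orthogroup_shape_mix weights must sum to 1")


@dataclass
class SimulatedComparison:
    """Two synthetic maps plus the planted truth."""

    map_a: ExpressionMap
    map_b: ExpressionMap
    orthopairs: PairSet
    orthogroups: list[OrthoGroup]
    #: pair -> {conserved, diverged, coexpressed_background}
    truth: dict[GenePair, str]
    matching: SampleMatching
    archetype_a: dict[str, int] = field(default_factory=dict)
    archetype_b: dict[str, int] = field(default_factory=dict)
    config: SimulationConfig | None = None

    def truth_label(self, pair: GenePair) -> str:
        """Planted label of any interspecific pair."""
        pair = GenePair(*pair)
        if pair in self.truth:
            return self.truth[pair]
        if self.archetype_a.get(pair.gene_a) == self.archetype_b.get(pair.gene_b):
            return "coexpressed_background"
        return "independent"

    def write(self, outdir) -> None:
        from pathlib import Path

        from .baseline import write_matching
        from .core import write_orthogroups, write_orthopairs

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.map_a.write_tsv(outdir / "map_a.tsv")
        self.map_b.write_tsv(outdir / "map_b.tsv")
        write_orthopairs(self.orthopairs, outdir / "orthopairs.tsv")
        write_orthogroups(
            self.orthogroups,
            outdir / "orthogroups.tsv",
            self.map_a.species_id,
            self.map_b.species_id,
        )
        write_matching(self.matching, outdir / "matching.tsv")
        pd.DataFrame(
            [(p.gene_a, p.gene_b, lab) for p, lab in self.truth.items()],
            columns=["gene_a", "gene_b", "label"],
        ).to_csv(outdir / "truth.tsv", sep="\t", index=False)
        if self.config is not None:
            cfg = asdict(self.config)
            cfg["orthogroup_shape_mix"] = [
                [list(shape), w] for shape, w in self.config.orthogroup_shape_mix
            ]
            (outdir / "simulation_config.json").write_text(json.dumps(cfg, indent=2))


# ---------------------------------------------------------------------------
# latent archetypes
# ---------------------------------------------------------------------------

def _draw_archetypes(rng: np.random.Generator, n: int):
    """Smooth positive intensity curves over the organ axis.

    Each archetype is a small mixture of Gaussian bumps plus a low baseline;
    curves are normalized to mean 1 over a fine grid so gene magnitude and
    archetype shape stay independent.
    """
    grid = np.linspace(0, 1, 201)
    params = []
    for _ in range(n):
        n_bumps = int(rng.integers(1, 4))
        centers = rng.uniform(0, 1, n_bumps)
        widths = rng.uniform(0.04, 0.25, n_bumps)
        heights = rng.uniform(0.5, 2.0, n_bumps)
        baseline = rng.uniform(0.02, 0.1)
        curve = baseline + sum(
            h * np.exp(-0.5 * ((grid - c) / w) ** 2)
            for c, w, h in zip(centers, widths, heights)
        )
        scale = curve.mean()
        params.append((centers, widths, heights, baseline, scale))
    return params


def _eval_archetype(param, t: np.ndarray) -> np.ndarray:
    centers, widths, heights, baseline, scale = param
    curve = baseline + sum(
        h * np.exp(-0.5 * ((t - c) / w) ** 2)
        for c, w, h in zip(centers, widths, heights)
    )
    return curve / scale


def _label_positions(n_labels: int) -> np.ndarray:
    return (np.arange(n_labels) + 0.5) / n_labels


def _render_counts(
    rng: np.random.Generator,
    archetype_params,
    archetype_of: np.ndarray,
    magnitudes: np.ndarray,
    n_labels: int,
    replicates: int,
    dispersion: float,
    library_size: float,
    column_factor_sd: float,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Draw the count matrix of one species dataset."""
    t = _label_positions(n_labels)
    intensity = np.empty((len(archetype_of), n_labels))
    for k in np.unique(archetype_of):
        rows = archetype_of == k
        intensity[rows] = _eval_archetype(archetype_params[k], t)[None, :]
    mu_label = intensity * magnitudes[:, None]
    # scale so the expected column sum matches the library size on average
    mu_label *= library_size / mu_label.sum(axis=0).mean()
    cols = np.repeat(np.arange(n_labels), replicates)
    mu = mu_label[:, cols]
    col_factors = np.exp(rng.normal(0.0, column_factor_sd, size=mu.shape[1]))
    mu = np.clip(mu * col_factors[None, :], 1e-9, None)
    if dispersion < 1e-8:
        counts = rng.poisson(mu)
    else:
        shape = 1.0 / dispersion
        p = shape / (shape + mu)
        counts = rng.negative_binomial(shape, p)
    width = len(str(n_labels))
    labels = [f"s{j + 1:0{width}d}" for j in range(n_labels)]
    sample_ids = [
        f"{labels[j]}.{r + 1}" for j in range(n_labels) for r in range(replicates)
    ]
    col_labels = [labels[j] for j in range(n_labels) for _ in range(replicates)]
    return counts, sample_ids, col_labels


def _axis_matching(n_labels_a: int, n_labels_b: int, n_bins: int | None = None) -> SampleMatching:
    """Group sample labels of both species by coarse bins of the organ axis.

    Bins holding exactly one label per species become direct matches; others
    become group matches (minimal-residual candidates).
    """
    if n_bins is None:
        n_bins = max(2, min(n_labels_a, n_labels_b) // 3)
    ta = _label_positions(n_labels_a)
    tb = _label_positions(n_labels_b)
    wa = len(str(n_labels_a))
    wb = len(str(n_labels_b))
    direct = []
    groups = []
    for b in range(n_bins):
        lo, hi = b / n_bins, (b + 1) / n_bins
        la = [f"s{j + 1:0{wa}d}" for j in np.flatnonzero((ta >= lo) & (ta < hi))]
        lb = [f"s{j + 1:0{wb}d}" for j in np.flatnonzero((tb >= lo) & (tb < hi))]
        if not la or not lb:
            continue
        if len(la) == 1 and len(lb) == 1:
            direct.append((la[0], lb[0]))
        else:
            groups.append((frozenset(la), frozenset(lb)))
    return SampleMatching(direct=tuple(direct), groups=tuple(groups))


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _gene_ids(prefix: str, n: int) -> list[str]:
    width = len(str(n))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def simulate_species_pair(config: SimulationConfig) -> SimulatedComparison:
    """Simulate two species' maps with planted orthogroups and truth labels."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    arch = _draw_archetypes(rng, config.n_archetypes)
    genes_a = _gene_ids("A", config.n_genes_a)
    genes_b = _gene_ids("B", config.n_genes_b)

    mag_a = np.maximum(3.0, np.exp(rng.normal(np.log(30.0), 2.0, config.n_genes_a)))
    mag_b = np.maximum(3.0, np.exp(rng.normal(np.log(30.0), 2.0, config.n_genes_b)))
    arch_a = rng.integers(0, config.n_archetypes, config.n_genes_a)
    arch_b = rng.integers(0, config.n_archetypes, config.n_genes_b)

    # ---- orthogroup scaffold ------------------------------------------------
    budget_a = int(config.orthogroup_gene_fraction * config.n_genes_a)
    budget_b = int(config.orthogroup_gene_fraction * config.n_genes_b)
    shapes = [s for s, _ in config.orthogroup_shape_mix]
    weights = np.array([w for _, w in config.orthogroup_shape_mix])
    next_a = 0
    next_b = 0
    orthogroups: list[OrthoGroup] = []
    truth: dict[GenePair, str] = {}
    orthopair_list: list[GenePair] = []
    gid = 0
    while True:
        na, nb = shapes[rng.choice(len(shapes), p=weights)]
        if next_a + na > budget_a or next_b + nb > budget_b:
            break
        ga = genes_a[next_a : next_a + na]
        gb = genes_b[next_b : next_b + nb]
        next_a += na
        next_b += nb
        gid += 1
        ancestral = int(rng.integers(0, config.n_archetypes))
        ancestral_mag = np.maximum(3.0, np.exp(rng.normal(np.log(30.0), 2.0)))
        # the first A gene anchors the ancestral profile; every other member
        # retains it with the conservation rate, so 1x1 pairs are conserved
        # with exactly that probability
        for j in range(na):
            i = next_a - na + j
            retained = j == 0 or rng.random() < config.conservation_rate
            arch_a[i] = ancestral if retained else int(
                rng.integers(0, config.n_archetypes)
            )
            mag_a[i] = ancestral_mag * np.exp(
                rng.normal(0.0, config.magnitude_jitter_sd)
            )
        for j in range(nb):
            i = next_b - nb + j
            retained = rng.random() < config.conservation_rate
            arch_b[i] = ancestral if retained else int(
                rng.integers(0, config.n_archetypes)
            )
            mag_b[i] = ancestral_mag * np.exp(
                rng.normal(0.0, config.magnitude_jitter_sd)
            )
        group = OrthoGroup(f"OG{gid:05d}", frozenset(ga), frozenset(gb))
        orthogroups.append(group)
        for pair in group.all_pairs():
            ia = int(pair.gene_a[1:]) - 1
            ib = int(pair.gene_b[1:]) - 1
            truth[pair] = (
                "conserved" if arch_a[ia] == arch_b[ib] else "diverged"
            )
        if (na, nb) == (1, 1):
            orthopair_list.append(GenePair(ga[0], gb[0]))

    # ---- coexpressed background among unassigned genes ----------------------
    free_a = list(range(next_a, config.n_genes_a))
    free_b = list(range(next_b, config.n_genes_b))
    if free_a:
        for ib in free_b:
            if rng.random() < config.coexpressed_background_rate:
                ia = int(rng.choice(free_a))
                arch_b[ib] = arch_a[ia]
                truth[GenePair(genes_a[ia], genes_b[ib])] = "coexpressed_background"

    counts_a, samples_a, labels_a = _render_counts(
        rng, arch, arch_a, mag_a, config.n_sample_labels_a,
        config.replicates_per_label, config.dispersion, config.library_size,
        config.column_factor_sd,
    )
    counts_b, samples_b, labels_b = _render_counts(
        rng, arch, arch_b, mag_b, config.n_sample_labels_b,
        config.replicates_per_label, config.dispersion, config.library_size,
        config.column_factor_sd,
    )
    map_a = ExpressionMap(
        "speciesA",
        pd.DataFrame(counts_a, index=genes_a, columns=samples_a),
        sample_labels=labels_a,
    )
    map_b = ExpressionMap(
        "speciesB",
        pd.DataFrame(counts_b, index=genes_b, columns=samples_b),
        sample_labels=labels_b,
    )
    return SimulatedComparison(
        map_a=map_a,
        map_b=map_b,
        orthopairs=PairSet(orthopair_list, label="positive"),
        orthogroups=orthogroups,
        truth=truth,
        matching=_axis_matching(config.n_sample_labels_a, config.n_sample_labels_b),
        archetype_a={g: int(k) for g, k in zip(genes_a, arch_a)},
        archetype_b={g: int(k) for g, k in zip(genes_b, arch_b)},
        config=config,
    )


def simulate_self_comparison(config: SimulationConfig) -> SimulatedComparison:
    """One gene set rendered into two independently noised datasets.

    Positive pairs are each gene matched with itself across the two datasets
    (the functional equivalence is known by construction), the analogue of
    comparing a species' atlas against an independent expression dataset of
    the same species. Sample-label sets differ between the datasets.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    arch = _draw_archetypes(rng, config.n_archetypes)
    n = config.n_genes_a
    genes = _gene_ids("G", n)
    mag = np.maximum(3.0, np.exp(rng.normal(np.log(30.0), 2.0, n)))
    arch_of = rng.integers(0, config.n_archetypes, n)

    counts_a, samples_a, labels_a = _render_counts(
        rng, arch, arch_of, mag, config.n_sample_labels_a,
        config.replicates_per_label, config.dispersion, config.library_size,
        config.column_factor_sd,
    )
    counts_b, samples_b, labels_b = _render_counts(
        rng, arch, arch_of, mag, config.n_sample_labels_b,
        config.replicates_per_label, config.dispersion, config.library_size,
        config.column_factor_sd,
    )
    map_a = ExpressionMap(
        "datasetA",
        pd.DataFrame(counts_a, index=genes, columns=samples_a),
        sample_labels=labels_a,
    )
    map_b = ExpressionMap(
        "datasetB",
        pd.DataFrame(counts_b, index=genes, columns=samples_b),
        sample_labels=labels_b,
    )
    pairs = [GenePair(g, g) for g in genes]
    groups = [
        OrthoGroup(f"SG{i + 1:05d}", frozenset([g]), frozenset([g]))
        for i, g in enumerate(genes)
    ]
    truth = {p: "conserved" for p in pairs}
    arch_map = {g: int(k) for g, k in zip(genes, arch_of)}
    return SimulatedComparison(
        map_a=map_a,
        map_b=map_b,
        orthopairs=PairSet(pairs, label="positive"),
        orthogroups=groups,
        truth=truth,
        matching=_axis_matching(config.n_sample_labels_a, config.n_sample_labels_b),
        archetype_a=arch_map,
        archetype_b=dict(arch_map),
        config=config,
    )
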