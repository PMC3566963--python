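"""Synthetic hierarchies, count matrices and metadata with known ground truth.

The generator emulates the standard inputs of a shotgun-metagenomics
comparison — a leveled annotation hierarchy, a features x samples count
matrix and a sample metadata table — at desk scale, with the truth recorded
so recovery can be measured. Counts follow a Dirichlet-multinomial scheme:
leaf base proportions are drawn once from a symmetric Dirichlet, a chosen
set of "spiked" leaves has its proportion multiplied by a fold factor in
one group (renormalized), optional per-sample gamma weighting adds
overdispersion, and each sample's counts are multinomial at a fixed
sequencing depth. Two equal-size groups ("caseA"/"caseB") are written to
the metadata together with one numerical covariate constructed to correlate
(Pearson rho ~ 0.8 in expectation) with a designated feature.

Defaults mirror a small but realistic gut-metagenome benchmark: 200 leaf
features over 3 levels, 20 samples per group, 10 spiked leaves at fold 4,
depth 50,000, no extra dispersion.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .abundance import AbundanceTable
from .errors import UsageError
from .hierarchy import HierarchyDB, parse_hierarchy

__all__ = ["FixtureConfig", "generate_hierarchy", "generate_abundance", "simulate_dataset"]

GROUP_A = "caseA"
GROUP_B = "caseB"


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs of the synthetic benchmark; same seed, same outputs."""

    n_leaves: int = 200
    n_levels: int = 3
    branching: int = 4  # children per parent when building the tree skeleton
    multi_parent_fraction: float = 0.1  # chance a node gains a second parent
    n_samples_per_group: int = 20
    n_spiked: int = 10
    spike_fold_change: float = 4.0
    sequencing_depth: int = 50_000
    dispersion: float = 0.0  # gamma overdispersion of per-sample proportions
    dirichlet_alpha: float = 0.5  # symmetric concentration of base proportions
    rng_seed: int = 0

    def __post_init__(self):
        if min(self.n_leaves, self.n_levels, self.branching,
               self.n_samples_per_group, self.sequencing_depth) < 1:
            raise UsageError("all fixture sizes must be positive")
        if self.n_levels < 2:
            raise UsageError("hierarchy needs at least 2 levels")
        if not 0 <= self.multi_parent_fraction <= 1:
            raise UsageError("multi_parent_fraction must be in [0, 1]")
        if self.n_spiked > self.n_leaves:
            raise UsageError(
                f"n_spiked={self.n_spiked} exceeds n_leaves={self.n_leaves}"
            )
        if self.n_spiked < 0 or self.dispersion < 0:
            raise UsageError("n_spiked and dispersion must be non-negative")
        if self.spike_fold_change < 1:
            raise UsageError("spike_fold_change must be >= 1")
        if self.branching ** (self.n_levels - 1) < 1:
            raise UsageError("branching incompatible with the level count")


def _level_sizes(config: FixtureConfig) -> list[int]:
    sizes = [config.n_leaves]
    for _ in range(1, config.n_levels):
        sizes.append(max(1, -(-sizes[-1] // config.branching)))  # ceil division
    return sizes


def generate_hierarchy(config: FixtureConfig) -> HierarchyDB:
    """Random leveled DAG: a tree skeleton plus optional second parents.

    Every node gets a primary parent assigned round-robin (so every parent
    has at least one child); with probability ``multi_parent_fraction`` a
    node gains one extra random parent at the same level up, producing the
    multi-membership structure typical of functional databases.
    """
    rng = np.random.default_rng(config.rng_seed)
    sizes = _level_sizes(config)
    level_names = ["feature"] + [f"level{l}" for l in range(1, config.n_levels)]
    names = [
        [f"{level_names[l]}_{i:04d}" for i in range(sizes[l])]
        for l in range(config.n_levels)
    ]
    parents: dict[str, list[str]] = {}
    for l in range(config.n_levels - 1):
        shuffled = rng.permutation(sizes[l])
        for rank, child_idx in enumerate(shuffled):
            child = names[l][child_idx]
            primary = rank % sizes[l + 1]
            parents[child] = [names[l + 1][primary]]
            if sizes[l + 1] >= 2 and rng.random() < config.multi_parent_fraction:
                extra = int(rng.integers(sizes[l + 1] - 1))
                if extra >= primary:
                    extra += 1
                parents[child].append(names[l + 1][extra])

    # emit lineage rows (root-first) covering every root-to-leaf path
    def paths_up(node: str, level: int) -> list[list[str]]:
        if level == config.n_levels - 1:
            return [[node]]
        return [[node] + tail for p in sorted(parents[node]) for tail in paths_up(p, level + 1)]

    rows = sorted(tuple(reversed(path)) for leaf in names[0] for path in paths_up(leaf, 0))
    buf = io.StringIO()
    buf.write("\t".join(reversed(level_names)) + "\n")
    for row in rows:
        buf.write("\t".join(row) + "\n")
    buf.seek(0)
    return parse_hierarchy(buf, orientation="root_first")


def generate_abundance(
    db: HierarchyDB, config: FixtureConfig
) -> tuple[AbundanceTable, pd.DataFrame, pd.DataFrame]:
    """Counts, metadata and the spike truth table for a two-group benchmark.

    Returns ``(table, metadata, truth)``: a counts AbundanceTable (columns
    group A samples then group B), a metadata frame with ``group`` and the
    correlated numerical covariate ``bmi``, and a truth frame listing each
    spiked leaf with its direction (+1 enriched in group A, -1 in group B)
    and the fold applied.
    """
    rng = np.random.default_rng(config.rng_seed + 1)
    leaves = [n.node_id for n in db.leaves()]
    n = len(leaves)
    if config.n_spiked > n:
        raise UsageError(f"n_spiked={config.n_spiked} exceeds {n} leaves in the database")
    base = rng.dirichlet(np.full(n, config.dirichlet_alpha))
    base = np.maximum(base, 1e-12)
    base /= base.sum()

    spiked_idx = np.sort(rng.choice(n, size=config.n_spiked, replace=False))
    directions = rng.choice([1, -1], size=config.n_spiked)

    props = {GROUP_A: base.copy(), GROUP_B: base.copy()}
    for idx, direction in zip(spiked_idx, directions):
        group = GROUP_A if direction > 0 else GROUP_B
        props[group][idx] *= config.spike_fold_change
    for group in props:
        props[group] /= props[group].sum()

    per_group = config.n_samples_per_group
    sample_ids = [f"{GROUP_A}_{i + 1:03d}" for i in range(per_group)] + [
        f"{GROUP_B}_{i + 1:03d}" for i in range(per_group)
    ]
    counts = np.empty((n, 2 * per_group), dtype=float)
    for j, sid in enumerate(sample_ids):
        p = props[GROUP_A] if j < per_group else props[GROUP_B]
        if config.dispersion > 0:
            weights = rng.gamma(1.0 / config.dispersion, config.dispersion, size=n)
            p = p * weights
            p = p / p.sum()
        counts[:, j] = rng.multinomial(config.sequencing_depth, p)

    table = AbundanceTable(
        pd.DataFrame(counts, index=pd.Index(leaves, name="feature_id"), columns=sample_ids),
        mode="counts",
        level=0,
        level_name=db.level_names[0],
    )

    # numerical covariate correlated with a designated feature's relative abundance
    target = int(spiked_idx[0]) if config.n_spiked else 0
    rel = counts[target] / counts.sum(axis=0)
    z = (rel - rel.mean()) / (rel.std() if rel.std() > 0 else 1.0)
    covariate = 26.0 + 4.0 * (0.8 * z + 0.6 * rng.standard_normal(len(sample_ids)))
    metadata = pd.DataFrame(
        {
            "group": [GROUP_A] * per_group + [GROUP_B] * per_group,
            "bmi": np.round(covariate, 2),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = pd.DataFrame(
        {
            "direction": directions,
            "fold_change": config.spike_fold_change,
            "covariate_target": [leaves[i] == leaves[target] for i in spiked_idx],
        },
        index=pd.Index([leaves[i] for i in spiked_idx], name="feature_id"),
    )
    return table, metadata, truth


def simulate_dataset(config: FixtureConfig, outdir) -> dict[str, str]:
    """Write hierarchy/abundance/metadata/truth files; returns their paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    db = generate_hierarchy(config)
    table, metadata, truth = generate_abundance(db, config)
    paths = {
        "hierarchy": str(outdir / "hierarchy.tsv"),
        "abundance": str(outdir / "abundance.tsv"),
        "metadata": str(outdir / "metadata.tsv"),
        "truth": str(outdir / "truth.tsv"),
    }
    db.write_lineage(paths["hierarchy"])
    table.data.to_csv(paths["abundance"], sep="\t", index_label="feature_id")
    metadata.to_csv(paths["metadata"], sep="\t", index_label="sample_id")
    truth.to_csv(paths["truth"], sep="\t", index_label="feature_id")
    return paths
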