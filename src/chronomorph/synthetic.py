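"""Synthetic study systems: pure-birth time trees with fossil tips, Brownian
traits with a tunable signal dial, and specimen-level measurement tables.

The default configuration emulates the structure of a clade-wide cranial
morphometric study: ~50 species (a third of them fossil) on a time tree ~30
Myr deep, ~29 positive linear measurements per specimen, ~330 specimens
grouped into ~11 clade-based lineages, species-level Brownian trait means on
a log scale, within-species noise, and a multiplicative per-specimen size
factor.  All generators are deterministic under the configured seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .tree import CalibrationRow, CalibrationTable, TimeTree, TreeError

__all__ = ["SimConfig", "sim_birth_tree", "sim_bm_traits",
           "sim_specimen_table", "assign_lineages", "simulate_study"]


@dataclass
class SimConfig:
    """Parameters of the synthetic study system (ages in Ma, rates per Myr)."""

    seed: int
    n_tips: int = 52
    birth_rate: float = 1.0
    tree_depth: float = 30.0          # root age after rescaling, Ma
    fossil_fraction: float = 0.35
    fossil_age_range_width: float = 1.5
    node_date_fraction: float = 0.3   # internal nodes with molecular dates
    n_traits: int = 29
    bm_sigma2: float = 0.01           # log-measurement scale, per Myr
    root_state: float = 0.0
    pagel_lambda: float = 1.0         # 1 = pure BM, 0 = star-equivalent
    n_groups: int = 11
    specimens_per_species: float = 6.4
    min_specimens: int = 2
    within_species_sd: float = 0.05   # log scale
    size_log_sd: float = 0.3
    baseline_log_range: tuple[float, float] = (2.0, 5.0)  # per-variable offsets

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_tips < 2 or self.birth_rate <= 0 or self.bm_sigma2 < 0:
            raise ValueError("invalid configuration")
        if not 0 <= self.pagel_lambda <= 1:
            raise ValueError("pagel_lambda must be in [0, 1]")
        if not 0 <= self.fossil_fraction < 1:
            raise ValueError("fossil_fraction must be in [0, 1)")


def sim_birth_tree(cfg: SimConfig) -> tuple[TimeTree, CalibrationTable]:
    """Simulate an ultrametric pure-birth tree, convert a fraction of tips to
    fossils, and emit the matching calibration table.

    The tree is rescaled to ``cfg.tree_depth`` Ma root age.  Fossil tips are
    truncated at a uniform point along their terminal branch (bounded away
    from both ends) and receive a stratigraphic range of width
    ``fossil_age_range_width`` centered on the truncation age; extant tips get
    a first occurrence within their terminal branch and last occurrence 0.
    """
    rng = np.random.default_rng(cfg.seed)
    dtree = treesim.birth_death_tree(
        birth_rate=cfg.birth_rate, death_rate=0.0,
        num_extant_tips=cfg.n_tips, rng=random.Random(cfg.seed),
    )
    # extend tips by the waiting time to the (n+1)-th event so the youngest
    # cherry does not sit at zero branch length
    extra = float(np.random.default_rng(cfg.seed + 1).exponential(
        1.0 / (cfg.n_tips * cfg.birth_rate)
    ))
    for leaf in dtree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    for i, leaf in enumerate(dtree.leaf_node_iter()):
        leaf.taxon.label = f"sp{i + 1:02d}"
    tree = TimeTree.from_dendropy(dtree)
    tree.assign_ages_from_lengths()
    scale = cfg.tree_depth / tree.root.age
    for node in tree.preorder():
        node.age *= scale
        if node.length is not None:
            node.length *= scale
    for tip in tree.tips():
        tip.age = 0.0  # ultrametric by construction; clear float residue

    tips = tree.tips()
    n_fossil = int(round(cfg.fossil_fraction * len(tips)))
    fossil_idx = set(rng.choice(len(tips), size=n_fossil, replace=False).tolist())
    rows: dict[str, CalibrationRow] = {}
    for i, tip in enumerate(tips):
        parent_age = tip.parent.age
        if i in fossil_idx:
            # truncate within (10%, 90%) of the terminal branch; the range is
            # symmetric about the truncation age (kept inside the branch and
            # above 0) so the midpoint date recovers the true tip age
            age = parent_age * rng.uniform(0.1, 0.9)
            half = min(0.5 * cfg.fossil_age_range_width,
                       0.4 * age, 0.5 * (parent_age - age))
            tip.age = age
            rows[tip.label] = CalibrationRow(
                tip.label, fo_ma=age + half, lo_ma=age - half
            )
        else:
            fo = parent_age * rng.uniform(0.2, 0.8)
            rows[tip.label] = CalibrationRow(tip.label, fo_ma=fo, lo_ma=0.0)

    # molecular divergence dates (true ages) for the root and a fraction of
    # internal nodes, keyed by a tip pair whose MRCA is that node — without
    # them the root's age would be driven entirely by tip occurrences
    internals = tree.internal_nodes()
    n_dated = int(round(cfg.node_date_fraction * (len(internals) - 1)))
    dated = [tree.root] + [
        internals[i] for i in
        rng.choice(range(1, len(internals)), size=n_dated, replace=False)
    ]
    node_dates = []
    for node in dated:
        left = next(n for n in _subtree_tips(node.children[0]))
        right = next(n for n in _subtree_tips(node.children[1]))
        node_dates.append(CalibrationRow(
            taxon=f"{left}|{right}", fo_ma=node.age, lo_ma=node.age,
            mrca_of=f"{left}|{right}", node_date_ma=node.age,
        ))
    return tree, CalibrationTable(rows=rows, node_dates=node_dates)


def _subtree_tips(node):
    if node.is_tip:
        yield node.label
    for child in node.children:
        yield from _subtree_tips(child)


def sim_bm_traits(tree: TimeTree, cfg: SimConfig) -> pd.DataFrame:
    """Brownian traits on a dated tree with a Pagel-lambda signal dial.

    Traits accrue independent normal increments of variance sigma^2 x duration
    along each branch.  ``pagel_lambda`` < 1 shrinks the shared (internal)
    path contributions of the tip covariance toward zero while keeping each
    tip's total variance: 1 is pure Brownian motion, 0 is equivalent to a
    star tree (no signal).
    """
    if not tree.has_ages:
        raise TreeError("sim_bm_traits requires a dated tree")
    rng = np.random.default_rng(cfg.seed + 2)
    labels = tree.tip_labels()
    V = tree.shared_path_matrix().to_numpy(dtype=float)
    lam = cfg.pagel_lambda
    Vl = lam * V + (1 - lam) * np.diag(np.diag(V))
    L = np.linalg.cholesky(Vl + 1e-12 * np.eye(len(V)))
    Z = rng.standard_normal((len(V), cfg.n_traits))
    traits = cfg.root_state + np.sqrt(cfg.bm_sigma2) * (L @ Z)
    return pd.DataFrame(
        traits, index=labels,
        columns=[f"trait{i + 1}" for i in range(cfg.n_traits)],
    )


def assign_lineages(tree: TimeTree, n_groups: int) -> pd.Series:
    """Clade-based lineage labels: cut the tree at the shallowest age at which
    it splits into >= n_groups subtrees and label tips by subtree."""
    nodes = sorted(tree.internal_nodes(), key=lambda n: -n.age)
    if n_groups > len(tree.tips()):
        raise ValueError("more groups than tips")
    # the clades hanging below the (n_groups - 1) oldest internal nodes
    cut = set(id(n) for n in nodes[: n_groups - 1])
    labels: dict[str, str] = {}
    counter = [0]

    def _walk(node, current):
        if id(node) in cut:
            for child in node.children:
                _walk(child, None)
            return
        if current is None:
            counter[0] += 1
            current = f"lineage{counter[0]:02d}"
        if node.is_tip:
            labels[node.label] = current
        for child in node.children:
            _walk(child, current)

    _walk(tree.root, None)
    return pd.Series(labels, name="lineage")


def sim_specimen_table(
    tree: TimeTree, cfg: SimConfig, traits: Optional[pd.DataFrame] = None
):
    """Specimen-level positive measurement table from species trait means.

    Species means (Brownian, log scale) plus per-variable baseline offsets are
    exponentiated, then each specimen multiplies them by within-species
    lognormal noise and a single lognormal size factor — so measurements are
    positive by construction and the size factor cancels exactly under the
    Mosimann transform.
    """
    from .shape import MeasurementTable

    if traits is None:
        traits = sim_bm_traits(tree, cfg)
    rng = np.random.default_rng(cfg.seed + 3)
    lineages = assign_lineages(tree, cfg.n_groups)
    baselines = rng.uniform(*cfg.baseline_log_range, size=traits.shape[1])

    rows = []
    for species in traits.index:
        n_spec = max(cfg.min_specimens, rng.poisson(cfg.specimens_per_species))
        mean_log = traits.loc[species].to_numpy() + baselines
        for s in range(n_spec):
            noise = rng.normal(0.0, cfg.within_species_sd, size=len(mean_log))
            size = np.exp(rng.normal(0.0, cfg.size_log_sd))
            vals = np.exp(mean_log + noise) * size
            row = {"specimen": f"{species}_{s + 1:02d}", "species": species,
                   "lineage": lineages[species]}
            row.update({f"var{j + 1}": v for j, v in enumerate(vals)})
            rows.append(row)
    return MeasurementTable(pd.DataFrame(rows))


def simulate_study(cfg: SimConfig):
    """One call for the full synthetic study: (tree, calibration, species
    trait means, specimen table)."""
    tree, cal = sim_birth_tree(cfg)
    traits = sim_bm_traits(tree, cfg)
    table = sim_specimen_table(tree, cfg, traits=traits)
    return tree, cal, traits, table
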