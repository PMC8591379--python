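"""Synthetic phylogenies and trait datasets.

Generates data with the statistical structure the allometry analysis
assumes: a pure-birth (Yule) tree scaled to unit depth; log10 body mass
drawn uniformly (exogenous to the phylogeny by default); log10 minimum
dominant frequency following a linear allometry with phylogenetically
correlated residual noise (Brownian motion attenuated by a Pagel's-lambda
factor); and a log-scale frequency range, so that MaxDF = MinDF + Range is
always strictly greater than MinDF.  A configurable number of monophyletic
clades is designated as VPL and receives a directional mean shift
(``delta`` on MinDF, ``delta_range`` on RangeDF), emulating the
vocal-learner deviations the pipeline is designed to detect.

Default parameters mirror the study conditions: 164 species, allometric
exponent -0.37, four VPL clades holding ~35% of tips (58/164).
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim
from scipy import linalg

from .covariance import bm_vcv, pagel_transform
from .traits import derive_features, validate_trait_table
from .trees import Phylogeny, write_newick

__all__ = [
    "SimulationConfig",
    "simulate_tree",
    "simulate_bm_on_tree",
    "simulate_allometric_dataset",
    "write_dataset",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic allometry dataset.

    delta is the VPL-clade mean shift on log10 MinDF (positive = upward);
    delta_range shifts log10 RangeDF independently, allowing distinct
    MinDF vs RangeDF outlier patterns.  mass_range is in log10 grams
    (default ~3 g to ~30 t); sigma2 is the Brownian rate of the residual
    trait on the unit-depth tree (so also the marginal residual variance).
    """

    n_species: int = 164
    seed: int = 0
    slope: float = -0.37
    intercept: float = 2.7
    sigma2: float = 0.04
    lambda_true: float = 0.8
    n_vpl_clades: int = 4
    vpl_fraction: float = 58 / 164
    delta: float = 0.0
    delta_range: float = 0.0
    mass_range: tuple[float, float] = (0.5, 7.5)
    range_intercept: float = 2.5
    range_slope: float = -0.07
    mass_phylogenetic: bool = False

    def __post_init__(self):
        if self.n_species < 4:
            raise ValueError("n_species must be >= 4")
        if not 0.0 <= self.vpl_fraction < 1.0:
            raise ValueError("vpl_fraction must be in [0, 1)")
        if not 0.0 <= self.lambda_true <= 1.0:
            raise ValueError("lambda_true must be in [0, 1]")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")
        if not np.isfinite(self.delta) or not np.isfinite(self.delta_range):
            raise ValueError("delta must be finite")


def simulate_tree(n: int, seed: int) -> Phylogeny:
    """Pure-birth (Yule) tree with ``n`` tips, scaled to unit total depth."""
    if n < 2:
        raise ValueError("need at least 2 tips")
    rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n, rng=rng,
    )
    # the simulator stops at the n-th birth, leaving zero-length pendant
    # edges; extend all tips by a draw of the waiting time to the next
    # birth so the covariance matrix stays non-singular (still ultrametric)
    extra = rng.expovariate(float(n))
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"sp{i:04d}"
    phylo = Phylogeny(tree)
    depth = phylo.max_depth()
    if depth <= 0:  # pragma: no cover - birth-death trees have positive depth
        raise RuntimeError("degenerate simulated tree")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / depth
    return Phylogeny(tree)


def simulate_bm_on_tree(tree: Phylogeny, sigma2: float, seed: int,
                        root_value: float = 0.0,
                        lambda_: float = 1.0) -> pd.Series:
    """Brownian-motion tip values: one draw from N(root, sigma2 * V_lambda).

    Sampled through the Cholesky factor of the (lambda-attenuated) BM
    covariance matrix; indexed by tip name.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    V = bm_vcv(tree)
    if lambda_ != 1.0:
        V = pagel_transform(V, lambda_)
    rng = np.random.default_rng(seed)
    n = len(V.species)
    L = linalg.cholesky(V.values + 1e-12 * np.eye(n), lower=True)
    z = root_value + np.sqrt(sigma2) * (L @ rng.standard_normal(n))
    return pd.Series(z, index=list(V.species))


def _choose_vpl_clades(tree: Phylogeny, n_clades: int,
                       fraction: float) -> list[frozenset]:
    """Pick ``n_clades`` disjoint monophyletic groups totalling ~fraction of tips.

    Greedy: each pick targets an equal share of the remaining tip budget
    and takes the disjoint clade (2 tips to half the tree) whose size is
    closest to that share.
    """
    n = tree.n_tips
    target_total = int(round(fraction * n))
    if n_clades == 0 or target_total == 0:
        return []
    clades = [c for c in tree.clade_tip_sets() if 2 <= len(c) <= max(2, n // 2)]
    picked: list[frozenset] = []
    for k in range(n_clades):
        remaining = n_clades - k
        budget = max(target_total - sum(len(p) for p in picked), remaining)
        share = budget / remaining
        avail = [c for c in clades if all(c.isdisjoint(p) for p in picked)]
        if not avail:
            raise ValueError(
                f"cannot place {n_clades} disjoint VPL clades at fraction "
                f"{fraction}; try fewer clades or a smaller fraction"
            )
        picked.append(min(avail, key=lambda c: (abs(len(c) - share), sorted(c))))
    achieved = sum(len(p) for p in picked)
    if abs(achieved - target_total) > max(2, 0.25 * target_total):
        feasible = achieved / n
        raise ValueError(
            f"vpl_fraction {fraction} unattainable with {n_clades} disjoint "
            f"clades on this tree (closest achievable ~{feasible:.2f}); "
            "try a smaller fraction or more clades"
        )
    return picked


def simulate_allometric_dataset(cfg: SimulationConfig):
    """Simulate (tree, trait table, truth record) under ``cfg``.

    The truth record stores every parameter, the VPL clade memberships and
    the per-tip injected deviation, for downstream power/calibration
    checks against known ground truth.
    """
    master = np.random.SeedSequence(cfg.seed)
    s_tree, s_mass, s_noise1, s_noise2 = (
        int(s.generate_state(1)[0] % (2 ** 31)) for s in master.spawn(4))
    tree = simulate_tree(cfg.n_species, s_tree)
    tips = tree.tips

    vpl_clades = _choose_vpl_clades(tree, cfg.n_vpl_clades, cfg.vpl_fraction)
    vpl_tips = set().union(*vpl_clades) if vpl_clades else set()
    clade_label = {}
    for i, clade in enumerate(sorted(vpl_clades, key=lambda c: sorted(c)), 1):
        for t in clade:
            clade_label[t] = f"vpl_clade_{i}"
    # remaining tips grouped by the root child they descend from
    seed_node = tree.tree.seed_node
    for j, child in enumerate(seed_node.child_nodes(), 1):
        for leaf in child.leaf_iter():
            clade_label.setdefault(leaf.taxon.label, f"background_{j}")

    rng_mass = np.random.default_rng(s_mass)
    if cfg.mass_phylogenetic:
        bm = simulate_bm_on_tree(tree, 1.0, s_mass).loc[tips].to_numpy()
        lo, hi = cfg.mass_range
        span = bm.max() - bm.min()
        log_mass = lo + (bm - bm.min()) / (span if span > 0 else 1.0) * (hi - lo)
    else:
        log_mass = rng_mass.uniform(*cfg.mass_range, size=len(tips))

    noise1 = simulate_bm_on_tree(tree, cfg.sigma2, s_noise1,
                                 lambda_=cfg.lambda_true).loc[tips].to_numpy()
    noise2 = simulate_bm_on_tree(tree, cfg.sigma2, s_noise2,
                                 lambda_=cfg.lambda_true).loc[tips].to_numpy()
    is_vpl = np.array([t in vpl_tips for t in tips])
    dev_min = cfg.delta * is_vpl
    dev_range = cfg.delta_range * is_vpl

    log_min = cfg.intercept + cfg.slope * log_mass + noise1 + dev_min
    log_range = (cfg.range_intercept + cfg.range_slope * log_mass
                 + noise2 + dev_range)
    min_df = 10.0 ** log_min
    max_df = min_df + 10.0 ** log_range

    table = pd.DataFrame({
        "species": tips,
        "body_mass_g": 10.0 ** log_mass,
        "min_df_hz": min_df,
        "max_df_hz": max_df,
        "clade": [clade_label[t] for t in tips],
        "is_vpl": is_vpl,
    })
    table = validate_trait_table(derive_features(table), tree=tree)

    truth = {
        "config": asdict(cfg),
        "vpl_clades": [sorted(c) for c in sorted(vpl_clades, key=lambda c: sorted(c))],
        "n_vpl": int(is_vpl.sum()),
        "per_tip_deviation_min": {t: float(d) for t, d in zip(tips, dev_min)},
        "per_tip_deviation_range": {t: float(d) for t, d in zip(tips, dev_range)},
        "child_seeds": {"tree": s_tree, "mass": s_mass,
                        "noise_min": s_noise1, "noise_range": s_noise2},
    }
    return tree, table, truth


def write_dataset(out_dir, tree: Phylogeny, table: pd.DataFrame, truth: dict) -> None:
    """Write Newick + trait CSV + truth JSON (deterministic byte-for-byte)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_newick(tree, out / "tree.nwk")
    cols = ["species", "body_mass_g", "min_df_hz", "max_df_hz", "clade", "is_vpl"]
    with open(out / "traits.csv", "w", newline="\n") as fh:
        fh.write(",".join(cols) + "\n")
        for _, row in table[cols].iterrows():
            fh.write(
                f"{row['species']},{row['body_mass_g']:.12g},"
                f"{row['min_df_hz']:.12g},{row['max_df_hz']:.12g},"
                f"{row['clade']},{bool(row['is_vpl'])}\n"
            )
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
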