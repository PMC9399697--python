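"""Synthetic data with the statistical structure the analyses assume.

Generates (a) birth-death trees with fossil tips and matching occurrence
tables, (b) locomotor states evolved under the equal-rates Markov model,
(c) specimen-level 15-measurement tables whose species-level log-shape
means combine a class signature with a phylogenetic component of tunable
Pagel's lambda, and (d) continuous traits drawn from any of the five
size-evolution models.  Every generator is reproducible from its seed and
its output passes the corresponding module's input validation, so the full
pipeline is testable without any downloaded data.

Defaults mirror the study conditions of the empirical analysis this
package automates: 139 species in 8 locomotor classes sampled by ~343
specimens, lambda = 0.1, and a directional-drift size model.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

import dendropy

from . import comparative, treeops
from .morphometrics import LOCOMOTOR_CLASSES, MEASUREMENT_NAMES

logger = logging.getLogger(__name__)


def class_offsets() -> pd.DataFrame:
    """Per-class 15-variable log-shape offsets (rows centred), from the
    versioned fixture file shipped with the package."""
    with resources.files("locomorph.data").joinpath("class_offsets.json").open() as fh:
        raw = json.load(fh)
    df = pd.DataFrame.from_dict(raw["offsets"], orient="index", columns=raw["measurements"])
    return df


@dataclass
class SimConfig:
    n_species: int = 139
    classes: tuple[str, ...] = LOCOMOTOR_CLASSES
    specimens_extra_mean: float = 1.5   # specimens per species = 1 + Poisson
    lambda_true: float = 0.1
    within_sd: float = 0.05             # specimen-level log-shape noise
    phylo_sd: float = 0.05              # SD of the phylogenetic component
    class_sep: float = 3.0              # pairwise class separation, in species-level SD units
    offset_mode: str = "ecomorph"       # "ecomorph" fixture or "orthogonal" contrasts
    birth: float = 0.1                  # per-lineage per-Myr
    death: float = 0.0
    fossil_fraction: float = 12.0 / 139.0
    mk_q: float = 0.05                  # per Myr
    continuous_model: str = "drift"
    continuous_params: dict = field(
        default_factory=lambda: {"sigma2": 0.01, "z0": 1.0, "h": 0.01}
    )
    size_log10_range: float = 1.5       # per-specimen size factors, +- decades
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.lambda_true <= 1.0:
            raise ValueError("lambda_true must be in [0, 1]")
        if min(self.within_sd, self.phylo_sd, self.birth) < 0 or self.death < 0:
            raise ValueError("rates and SDs must be >= 0")


# ---------------------------------------------------------------------------
# Trees

def sim_tree(
    n_species: int = 50,
    birth: float = 0.1,
    death: float = 0.0,
    fossil_fraction: float = 0.0,
    seed: int = 0,
    horizon: float | None = None,
    max_retries: int = 100,
) -> tuple[dendropy.Tree, pd.DataFrame]:
    """Forward birth-death simulation; returns a dated tree + occurrences.

    Stops when ``n_species`` lineages are simultaneously extant, or at the
    fixed time ``horizon`` if given.  Lineages that die before the present
    are retained as fossil tips; additionally a ``fossil_fraction`` of the
    extant tips is truncated before the present to emulate fossil sampling.
    Complete extinction triggers a resample (retry count logged).
    """
    rng = np.random.default_rng(seed)
    for attempt in range(max_retries):
        result = _bd_once(n_species, birth, death, horizon, rng)
        if result is not None:
            break
    else:
        raise RuntimeError(f"all lineages died in {max_retries} attempts")
    if attempt:
        logger.info("sim_tree resampled %d time(s) after total extinction", attempt)
    newick, tip_ages = result
    tree = treeops.tree_from_newick(newick)

    if fossil_fraction > 0:
        extant = [l for l in tree.leaf_node_iter() if tip_ages[l.taxon.label] == 0.0]
        n_trunc = int(round(fossil_fraction * len(extant)))
        for l in rng.choice(extant, size=n_trunc, replace=False):
            cut = rng.uniform(0.1, 0.5) * l.edge.length
            l.edge.length -= cut
            tip_ages[l.taxon.label] += cut

    depths = treeops.node_depths(tree)
    span = max(depths[l] + tip_ages[l.taxon.label] for l in tree.leaf_node_iter())
    for node in tree.preorder_node_iter():
        node.age = span - depths[node]
    occ = pd.DataFrame(
        {
            "taxon": list(tip_ages),
            "FAD": [tip_ages[t] for t in tip_ages],
            "LAD": [tip_ages[t] for t in tip_ages],
        }
    )
    return tree, treeops.validate_occurrences(occ)


def _bd_once(n_species, birth, death, horizon, rng):
    """One birth-death trajectory; returns (newick, tip ages) or None."""
    # lineage record: [parent_id, start_time, end_time, alive]
    lineages = {0: [None, 0.0, None, True]}
    children: dict[int, list[int]] = {0: []}
    alive = [0]
    t, next_id = 0.0, 1
    while True:
        total = len(alive) * (birth + death)
        if n_species is not None and horizon is None and len(alive) >= n_species:
            # run out the clock to the next would-be event so the stopping
            # rule leaves no zero-length terminal branches
            present = t + (rng.exponential(1.0 / total) if total > 0 else 1.0)
            break
        wait = rng.exponential(1.0 / total) if total > 0 else np.inf
        if horizon is not None and t + wait >= horizon:
            present = horizon
            break
        t += wait
        lin = alive[rng.integers(len(alive))]
        if rng.random() < birth / (birth + death) if death > 0 else True:
            lineages[lin][2] = t
            lineages[lin][3] = False
            for _ in range(2):
                lineages[next_id] = [lin, t, None, True]
                children[next_id] = []
                children[lin].append(next_id)
                alive.append(next_id)
                next_id += 1
            alive.remove(lin)
        else:
            lineages[lin][2] = t
            lineages[lin][3] = False
            alive.remove(lin)
        if not alive:
            return None
    for lin in alive:
        lineages[lin][2] = present
    # drop the root stem artefact when the first lineage never split
    tip_ids = [i for i, rec in lineages.items() if not children[i]]
    if len(tip_ids) < 2:
        return None
    names = {i: f"sp{j + 1:03d}" for j, i in enumerate(sorted(tip_ids))}
    tip_ages = {
        names[i]: present - lineages[i][2] for i in tip_ids
    }

    def render(i):
        length = lineages[i][2] - lineages[i][1]
        if not children[i]:
            return f"{names[i]}:{length:.10g}"
        inner = ",".join(render(c) for c in children[i])
        return f"({inner}):{length:.10g}"

    if children[0]:
        newick = "(" + ",".join(render(c) for c in children[0]) + ");"
    else:
        return None
    return newick, tip_ages


# ---------------------------------------------------------------------------
# Discrete states

def sim_locomotion(
    tree: dendropy.Tree,
    q: float,
    classes=LOCOMOTOR_CLASSES,
    seed: int = 0,
    return_internal: bool = False,
):
    """Evolve states by the equal-rates Markov process along the branches."""
    rng = np.random.default_rng(seed)
    classes = list(classes)
    k = len(classes)
    node_state: dict = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node_state[node] = int(rng.integers(k))
            continue
        parent = node_state[node.parent_node]
        t = node.edge.length or 0.0
        e = np.exp(-k * q * t)
        probs = np.full(k, (1.0 - e) / k)
        probs[parent] = (1.0 + (k - 1) * e) / k
        node_state[node] = int(rng.choice(k, p=probs))
    tips = pd.Series(
        {l.taxon.label: classes[node_state[l]] for l in tree.leaf_node_iter()}
    )
    if return_internal:
        return tips, {n: classes[s] for n, s in node_state.items()}
    return tips


# ---------------------------------------------------------------------------
# Measurements

def sim_measurements(
    tree: dendropy.Tree,
    states: pd.Series,
    config: SimConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Specimen-level measurement table with known class structure.

    Species-level log-shape mean = class signature (scaled to
    ``class_sep`` within-SD units) + a per-trait phylogenetic component
    drawn from MVN(0, phylo_sd^2 * C(lambda_true)) on the depth-normalized
    tree.  Specimen rows add iid within-species noise, are exponentiated,
    and multiplied by a random per-specimen size factor spanning
    ``size_log10_range`` decades so GM normalization has real work to do.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if config.offset_mode == "orthogonal":
        offsets = _orthogonal_offsets(sorted(states.unique()))
    elif config.offset_mode == "ecomorph":
        offsets = class_offsets()
    else:
        raise ValueError(f"unknown offset_mode {config.offset_mode!r}")
    unknown = set(states.unique()) - set(offsets.index)
    if unknown:
        raise ValueError(f"no class offsets for {sorted(unknown)}")
    species = list(states.index)
    p = len(MEASUREMENT_NAMES)

    C = treeops.vcv_matrix(tree, species).to_numpy()
    C = C / np.diag(C).mean()
    Clam = config.lambda_true * C
    np.fill_diagonal(Clam, np.diag(C))
    L = np.linalg.cholesky(Clam + 1e-12 * np.eye(len(species)))
    phylo = config.phylo_sd * (L @ rng.standard_normal((len(species), p)))

    # class_sep is in units of the species-level SD (phylogenetic +
    # within-species components combined)
    scale = config.class_sep * np.sqrt(config.phylo_sd**2 + config.within_sd**2)
    means = scale * offsets.loc[states[species]].to_numpy() + phylo

    rows = []
    for i, sp in enumerate(species):
        n_spec = 1 + rng.poisson(config.specimens_extra_mean)
        for j in range(n_spec):
            v = means[i] + config.within_sd * rng.standard_normal(p)
            size = 10.0 ** rng.uniform(-config.size_log10_range, config.size_log10_range)
            m = np.exp(v) * size
            rows.append(
                {
                    "specimen_id": f"{sp}_{j + 1}",
                    "species": sp,
                    "locomotion": states[sp],
                    **dict(zip(MEASUREMENT_NAMES, m)),
                }
            )
    return pd.DataFrame(rows)


def _orthogonal_offsets(classes: list[str]) -> pd.DataFrame:
    """Equidistant class offsets: normalized Helmert contrasts (orthogonal,
    zero-sum), scaled so every pair of classes sits at unit distance."""
    p = len(MEASUREMENT_NAMES)
    if len(classes) + 1 > p:
        raise ValueError("more classes than contrast dimensions")
    rows = []
    for j in range(1, len(classes) + 1):
        v = np.zeros(p)
        v[:j] = 1.0
        v[j] = -j
        rows.append(v / np.linalg.norm(v))
    M = np.vstack(rows) / np.sqrt(2.0)  # unit pairwise distance
    return pd.DataFrame(M, index=classes, columns=MEASUREMENT_NAMES)


# ---------------------------------------------------------------------------
# Continuous traits

def sim_continuous(
    tree: dendropy.Tree, model: str, params: dict, seed: int = 0
) -> pd.Series:
    """Draw one tip trait vector from the MVN implied by a trait model."""
    mu, V = comparative.model_cov(tree, model, params)
    rng = np.random.default_rng(seed)
    Vv = V.to_numpy()
    L = np.linalg.cholesky(Vv + 1e-12 * np.eye(len(Vv)))
    return pd.Series(mu + L @ rng.standard_normal(len(mu)), index=V.index)


# ---------------------------------------------------------------------------
# Bundles

@dataclass
class SimBundle:
    tree: dendropy.Tree
    occurrences: pd.DataFrame
    tip_states: pd.Series
    measurements: pd.DataFrame
    trait: pd.Series          # log10 LTRL-like continuous trait
    config: SimConfig


def simulate_dataset(config: SimConfig) -> SimBundle:
    """Full synthetic input bundle driven by one master seed."""
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(2**31, size=4)
    tree, occ = sim_tree(
        n_species=config.n_species,
        birth=config.birth,
        death=config.death,
        fossil_fraction=config.fossil_fraction,
        seed=int(seeds[0]),
    )
    states = sim_locomotion(tree, config.mk_q, config.classes, seed=int(seeds[1]))
    measurements = sim_measurements(tree, states, config, seed=int(seeds[2]))
    trait = sim_continuous(
        tree, config.continuous_model, config.continuous_params, seed=int(seeds[3])
    )
    return SimBundle(tree, occ, states, measurements, trait, config)
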