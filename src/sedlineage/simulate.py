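"""Synthetic sedimentary-DNA study generator.

Generates everything the downstream analyses consume, with known ground
truth: an ultrametric Yule tree over closely related lineages, Jukes–Cantor
sequences along it, a grid of lakes crossed between latitudinal transects
and an ordered tundra→taiga vegetation gradient, lineage occupancy driven
by a Gaussian niche response around Brownian-motion niche optima, a
sediment core with a declining Larix pollen curve, and clone libraries with
rare polymerase errors.

The scenario switch controls what structures occupancy:

* ``environment`` — niche optima live on the vegetation-type index, so
  related lineages occupy similar vegetation regardless of transect;
* ``geography`` — optima live on the transect index instead;
* ``null`` — occupancy is a constant Bernoulli rate, independent of both.

Defaults match the study design: 14 lineages over 21 lakes in 3 transects
× 4 vegetation types and 20 core horizons, with a clearly detectable niche
signal (Brownian variance 2.0 on a unit-height tree, niche width 0.5
category units, baseline occupancy 0.9).  :func:`strong_preset` raises the
lineage count to 23 (the larger fragment dataset) for scenario-recovery
power checks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from skbio import TreeNode

from .errors import InvalidArgumentError, SimulationError
from .seqproc import CloneLibrary, LineageSet, SequenceRecord

VEGETATION_TYPES = (
    "arctic_tundra",
    "single_tree_tundra",
    "forest_tundra",
    "northern_taiga",
)

SCENARIOS = ("environment", "geography", "null")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study; same config + seed → identical output."""

    n_lineages: int = 14
    seq_length: int = 67
    n_transects: int = 3
    n_vegetation_types: int = 4
    n_lakes: int = 21
    n_core_samples: int = 20
    mutation_rate: float = 0.04  # expected substitutions/site over a unit branch
    niche_signal: float = 2.0  # Brownian-trait variance per unit branch length
    occupancy_baseline: float = 0.9
    niche_width: float = 0.5  # in category-index units
    clone_count: int = 20
    clone_error_rate: float = 0.001
    n_pcr_replicates: int = 2
    larix_start: float = 6.0  # oldest horizons, percent of terrestrial pollen
    larix_end: float = 1.0  # youngest horizons
    larix_noise: float = 0.3
    scenario: str = "environment"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_lineages", "n_transects", "n_vegetation_types", "n_lakes",
                     "n_core_samples"):
            if getattr(self, name) < 2:
                raise InvalidArgumentError(f"{name} must be >= 2")
        if self.seq_length < 1:
            raise InvalidArgumentError("seq_length must be >= 1")
        if self.mutation_rate < 0:
            raise InvalidArgumentError("mutation_rate must be >= 0")
        if not (0 <= self.occupancy_baseline <= 1):
            raise InvalidArgumentError("occupancy_baseline must be in [0, 1]")
        if not (0 <= self.clone_error_rate < 1):
            raise InvalidArgumentError("clone_error_rate must be in [0, 1)")
        if self.niche_width <= 0 or self.niche_signal < 0:
            raise InvalidArgumentError("niche_width > 0 and niche_signal >= 0 required")
        if self.scenario not in SCENARIOS:
            raise InvalidArgumentError(f"scenario must be one of {SCENARIOS}")


def strong_preset(scenario: str = "environment", seed: int = 0, **overrides) -> SimulationConfig:
    """The clearly-detectable study condition used for scenario-recovery checks.

    23 lineages (the size of the longer-fragment lineage set), a sharp
    Gaussian niche (width 0.5 category units, baseline occupancy 0.9) and
    Brownian niche variance 2.0 on the unit-height tree — related lineages
    share niches while optima still spread across the whole gradient.
    """
    base = dict(n_lineages=23, niche_signal=2.0, niche_width=0.5,
                occupancy_baseline=0.9, scenario=scenario, seed=seed)
    base.update(overrides)
    return SimulationConfig(**base)


@dataclass
class ScenarioTruth:
    """Ground truth retained for parameter-recovery tests."""

    optima: pd.Series  # lineage -> niche optimum on the scenario's category axis
    lake_table: pd.DataFrame
    tree: TreeNode
    scenario: str
    core_larix: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lineage": self.optima.index, "optimum": self.optima.values})


@dataclass
class SimulatedDataset:
    """One complete synthetic study (spatial + temporal data + truth)."""

    tree: TreeNode
    lineages: LineageSet
    lake_table: pd.DataFrame
    occurrence: pd.DataFrame  # lineages × lakes, 0/1
    core_table: pd.DataFrame
    core_occurrence: pd.DataFrame  # lineages × horizons, 0/1
    truth: ScenarioTruth
    config: SimulationConfig


# ---------------------------------------------------------------------------
# Tree and sequences


def simulate_tree(n_lineages: int, seed: int | None = None, height: float = 1.0) -> TreeNode:
    """Ultrametric Yule (pure-birth) tree with unit root-to-tip height.

    Waiting times between successive splits are exponential with rate equal
    to the number of extant lineages; after the last split the tree is
    extended by one more exponential wait so every terminal branch has
    positive length, then rescaled to ``height``.
    """
    if n_lineages < 2:
        raise InvalidArgumentError("n_lineages must be >= 2")
    rng = np.random.default_rng(seed)
    root = TreeNode(name=None)
    birth: dict[int, float] = {id(root): 0.0}
    active = [root]
    t = 0.0
    first_split = None
    for k in range(1, n_lineages):
        t += rng.exponential(1.0 / k)
        if first_split is None:
            first_split = t
        node = active.pop(rng.integers(len(active)))
        left, right = TreeNode(), TreeNode()
        node.extend([left, right])
        birth[id(left)] = birth[id(right)] = t
        active.extend([left, right])
    t += rng.exponential(1.0 / n_lineages)
    # normalize so the (ultrametric) root-to-tip depth equals `height`
    scale = height / (t - first_split) if t > first_split else 1.0
    for node in root.traverse(include_self=False):
        end = birth.get(id(node.children[0]), t) if node.children else t
        node.length = (end - birth[id(node)]) * scale
    root.length = None
    width = max(2, len(str(n_lineages)))
    for i, tip in enumerate(root.tips(), start=1):
        tip.name = f"lineage_{i:0{width}d}"
    return root


def jc69_mismatch_probability(mu: float, t: float) -> float:
    """Expected per-site mismatch fraction after evolving for branch length t."""
    return 0.75 * (1.0 - np.exp(-4.0 * mu * t / 3.0))


def evolve_sequences(
    tree: TreeNode,
    seq_length: int,
    mutation_rate: float,
    seed: int | None = None,
    fragment_label: str | None = None,
) -> LineageSet:
    """Jukes–Cantor sequence evolution along the tree.

    The root sequence is uniform over A/C/G/T; down each branch every site
    substitutes independently with probability ¾(1 − e^(−4μt/3)), to one of
    the three other bases uniformly.
    """
    if seq_length < 1:
        raise InvalidArgumentError("seq_length must be >= 1")
    if mutation_rate < 0:
        raise InvalidArgumentError("mutation_rate must be >= 0")
    rng = np.random.default_rng(seed)
    root_seq = rng.integers(0, 4, size=seq_length)
    seqs: dict[str, np.ndarray] = {}

    def descend(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            t = child.length
            if t is None or not np.isfinite(t):
                raise InvalidArgumentError("tree has missing branch lengths")
            p = jc69_mismatch_probability(mutation_rate, t)
            child_seq = seq.copy()
            hits = np.nonzero(rng.random(seq_length) < p)[0]
            if hits.size:
                child_seq[hits] = (child_seq[hits] + rng.integers(1, 4, size=hits.size)) % 4
            if child.is_tip():
                seqs[child.name] = child_seq
            else:
                descend(child, child_seq)

    if tree.is_tip():
        seqs[tree.name] = root_seq
    else:
        descend(tree, root_seq)
    ids = [t.name for t in tree.tips()] or [tree.name]
    label = fragment_label or f"sim_{seq_length}"
    decode = {0: "A", 1: "C", 2: "G", 3: "T"}
    strings = ["".join(decode[b] for b in seqs[i]) for i in ids]
    return LineageSet(ids, strings, label)


# ---------------------------------------------------------------------------
# Lakes, niches and occupancy


def simulate_lakes(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Lake metadata: transect blocks crossed with a cycling vegetation gradient.

    Lakes are split into contiguous transect blocks while vegetation types
    cycle through the ordered gradient, so transect and vegetation are close
    to orthogonal — as in a design sampling every vegetation type within
    every transect.  Limnological columns are decorative draws; Larix pollen
    percentage increases (noisily) toward the taiga end.
    """
    n = config.n_lakes
    per = int(np.ceil(n / config.n_transects))
    transect_idx = np.minimum(np.arange(n) // per, config.n_transects - 1)
    # identical vegetation composition in every transect block: a lineage's
    # expected affinity for the *other* factor is then the same whatever its
    # niche, so the two explanatory axes are crossed rather than confounded
    veg_idx = (np.arange(n) % per) % config.n_vegetation_types
    if config.n_vegetation_types == 4:
        veg_names = list(VEGETATION_TYPES)
    else:
        veg_names = [f"veg_{i + 1}" for i in range(config.n_vegetation_types)]
    larix = np.clip(
        0.5 + 1.3 * veg_idx + rng.normal(0, 0.5, size=n), 0.0, None
    )
    return pd.DataFrame(
        {
            "sample": [f"lake_{i + 1:02d}" for i in range(n)],
            "transect": [f"transect_{i + 1}" for i in transect_idx],
            "transect_index": transect_idx,
            "vegetation": [veg_names[i] for i in veg_idx],
            "vegetation_index": veg_idx,
            "ph": np.round(rng.normal(7.0, 0.6, size=n), 2),
            "conductivity": np.round(np.exp(rng.normal(3.7, 0.5, size=n)), 1),
            "larix_pct": np.round(larix, 2),
        }
    )


def brownian_optima(
    tree: TreeNode, variance: float, root_value: float, rng: np.random.Generator
) -> pd.Series:
    """Brownian-motion trait values at the tips (niche optima).

    Relatedness → niche similarity is built in: trait covariance between
    two tips equals ``variance`` times their shared path depth.
    """
    values: dict[str, float] = {}

    def descend(node: TreeNode, value: float) -> None:
        for child in node.children:
            v = value + rng.normal(0.0, np.sqrt(max(variance, 0.0) * child.length))
            if child.is_tip():
                values[child.name] = v
            else:
                descend(child, v)

    descend(tree, root_value)
    tips = [t.name for t in tree.tips()]
    return pd.Series([values[t] for t in tips], index=tips, name="optimum")


def _reflect(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold values into [lo, hi] by mirror reflection at the boundaries."""
    span = hi - lo
    x = np.mod(values - lo, 2 * span)
    return lo + np.where(x > span, 2 * span - x, x)


def make_truth(tree: TreeNode, lake_table: pd.DataFrame, config: SimulationConfig,
               rng: np.random.Generator) -> ScenarioTruth:
    k = (
        config.n_transects
        if config.scenario == "geography"
        else config.n_vegetation_types
    )
    optima = brownian_optima(tree, config.niche_signal, (k - 1) / 2.0, rng)
    # reflected Brownian motion: niche optima stay on the sampled gradient
    # (slightly beyond the outermost categories), so every lineage is
    # observable somewhere while relatedness -> niche similarity is kept
    optima = pd.Series(
        _reflect(optima.to_numpy(), -0.5, k - 0.5), index=optima.index, name="optimum"
    )
    return ScenarioTruth(optima=optima, lake_table=lake_table, tree=tree,
                         scenario=config.scenario)


def _presence_probability(
    optima: np.ndarray, positions: np.ndarray, baseline: float, width: float
) -> np.ndarray:
    gap = optima[:, None] - positions[None, :]
    return baseline * np.exp(-(gap**2) / (2.0 * width**2))


def simulate_occurrences(
    truth: ScenarioTruth,
    config: SimulationConfig,
    rng: np.random.Generator,
    max_retries: int = 100,
) -> pd.DataFrame:
    """Binary lineage × lake occupancy under the configured scenario.

    Environment/geography: P(present) follows a Gaussian niche response of
    the relevant category index around each lineage's optimum.  Null:
    constant baseline.  A lineage observed nowhere cannot enter any
    analysis, so all-zero rows are redrawn (bounded retries).
    """
    lakes = truth.lake_table
    lineages = list(truth.optima.index)
    if config.scenario == "null":
        prob = np.full((len(lineages), len(lakes)), config.occupancy_baseline)
    else:
        col = "transect_index" if config.scenario == "geography" else "vegetation_index"
        prob = _presence_probability(
            truth.optima.to_numpy(),
            lakes[col].to_numpy(dtype=float),
            config.occupancy_baseline,
            config.niche_width,
        )
    occ = (rng.random(prob.shape) < prob).astype(int)
    for _ in range(max_retries):
        empty = occ.sum(axis=1) == 0
        if not empty.any():
            break
        redraw = rng.random((int(empty.sum()), prob.shape[1])) < prob[empty]
        occ[empty] = redraw.astype(int)
    else:
        bad = [lineages[i] for i in np.nonzero(occ.sum(axis=1) == 0)[0]]
        raise SimulationError(
            f"lineages {bad} drew no occurrences in {max_retries} retries; "
            "their niche optima are far outside the sampled gradient "
            "(raise niche_width or occupancy_baseline)"
        )
    return pd.DataFrame(occ, index=lineages, columns=list(lakes["sample"]))


def larix_curve(config: SimulationConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Declining Larix pollen curve over core horizons, oldest (high) to youngest (low).

    Horizon k of n gets larix_start − (larix_start − larix_end)·k/(n−1) plus
    Gaussian noise, clipped at zero; index 0 is the oldest horizon.
    """
    n = config.n_core_samples
    base = config.larix_start - (config.larix_start - config.larix_end) * np.arange(n) / (n - 1)
    if rng is not None and config.larix_noise > 0:
        base = base + rng.normal(0.0, config.larix_noise, size=n)
    return np.clip(base, 0.0, None)


def simulate_core(
    truth: ScenarioTruth,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Core-horizon occupancy and sample table (depth, age, Larix %).

    The same Gaussian-niche rule drives presence, with Larix % as the
    environmental axis: each lineage's category-scale optimum is mapped
    linearly onto the Larix range (taiga-end optima → high Larix), and the
    niche width is rescaled the same way.  All-zero horizons are allowed;
    depth/age form monotone grids (mean sedimentation ≈ 0.019 cm/yr).
    """
    n = config.n_core_samples
    larix = larix_curve(config, rng)
    k = (
        config.n_transects
        if truth.scenario == "geography"
        else config.n_vegetation_types
    )
    span = config.larix_start - config.larix_end
    scale = span / (k - 1)
    larix_optima = config.larix_end + truth.optima.to_numpy() * scale
    width = config.niche_width * scale
    if truth.scenario == "null":
        prob = np.full((len(truth.optima), n), config.occupancy_baseline)
    else:
        prob = _presence_probability(
            larix_optima, larix, config.occupancy_baseline, width
        )
    occ = (rng.random(prob.shape) < prob).astype(int)
    depth = np.round(np.linspace(2.0, 132.0, n), 1)
    age = np.round(depth / 0.019).astype(int)
    # oldest horizon first in the larix curve; order the table youngest-first
    table = pd.DataFrame(
        {
            "sample": [f"horizon_{i + 1:02d}" for i in range(n)],
            "depth_cm": depth,
            "age_calBP": age,
            "larix_pct": np.round(larix[::-1], 2),
        }
    )
    occurrence = pd.DataFrame(
        occ[:, ::-1], index=list(truth.optima.index), columns=list(table["sample"])
    )
    truth.core_larix = larix[::-1]
    return occurrence, table


# ---------------------------------------------------------------------------
# Clone libraries


def simulate_clone_library(
    lineage_sequence: str,
    clone_count: int,
    clone_error_rate: float,
    seed: int | None = None,
    n_pcrs: int = 2,
    sample_id: str = "sample_01",
    template_id: str = "template",
) -> CloneLibrary:
    """Clones of one template with independent per-site polymerase errors.

    Each site substitutes to a uniformly chosen different base with
    probability ``clone_error_rate``; clones are tagged round-robin with one
    of ``n_pcrs`` independent PCR replicate ids.
    """
    if clone_count < 1:
        raise InvalidArgumentError("clone_count must be >= 1")
    if not (0 <= clone_error_rate < 1):
        raise InvalidArgumentError("clone_error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    decode = "ACGT"
    template = np.array([code[b] for b in lineage_sequence.upper()])
    records = []
    for c in range(clone_count):
        clone = template.copy()
        hits = np.nonzero(rng.random(clone.size) < clone_error_rate)[0]
        if hits.size:
            clone[hits] = (clone[hits] + rng.integers(1, 4, size=hits.size)) % 4
        records.append(
            SequenceRecord(
                id=f"{template_id}_clone_{c + 1:03d}",
                sequence="".join(decode[b] for b in clone),
                sample_id=sample_id,
                pcr_id=f"pcr_{c % n_pcrs + 1}",
            )
        )
    return CloneLibrary(records=records, sample_id=sample_id)


# ---------------------------------------------------------------------------
# Whole-study convenience


def simulate_dataset(config: SimulationConfig | None = None, **overrides) -> SimulatedDataset:
    """Generate a full synthetic study from one config (deterministic in seed)."""
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    seeds = np.random.SeedSequence(config.seed).spawn(5)
    tree = simulate_tree(config.n_lineages, np.random.default_rng(seeds[0]))
    lineages = evolve_sequences(
        tree, config.seq_length, config.mutation_rate, np.random.default_rng(seeds[1])
    )
    rng_lakes = np.random.default_rng(seeds[2])
    lake_table = simulate_lakes(config, rng_lakes)
    truth = make_truth(tree, lake_table, config, rng_lakes)
    occurrence = simulate_occurrences(truth, config, np.random.default_rng(seeds[3]))
    core_occurrence, core_table = simulate_core(
        truth, config, np.random.default_rng(seeds[4])
    )
    return SimulatedDataset(
        tree=tree,
        lineages=lineages,
        lake_table=lake_table,
        occurrence=occurrence,
        core_table=core_table,
        core_occurrence=core_occurrence,
        truth=truth,
        config=config,
    )
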