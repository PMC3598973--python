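"""Synthetic study-data generators.

Everything the pipeline consumes can be generated here with known ground
truth: Yule (pure-birth) chronograms, Brownian-motion traits with optional
lambda dilution and clade-specific rate multipliers, tapered-helix landmark
paths with quadrature-oracle arc lengths, and audiogram calibration tables
built from stated generative regression curves plus Gaussian noise.  All
generators are bit-reproducible given (config, seed).

The defaults encode the study conditions the pipeline targets: a
placental-mammal-style allometry (log10 membrane length on log10 cube-root
mass, slope 0.498, intercept 0.717), an echolocator group offset above that
line, turn counts increasing with relative membrane length, and call
frequencies tied to membrane length and turns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError, DomainError
from .hearing import CallFreqModel, load_builtin_model
from .morphometry import LandmarkPath, relative_membrane_length
from .phylo_io import Phylogeny
from . import comparative

__all__ = [
    "SimulationConfig",
    "StudyDataset",
    "simulate_yule_tree",
    "simulate_bm_traits",
    "generate_spiral_path",
    "generate_study_dataset",
    "SYNTHETIC_HEARING_CURVES",
]


def _rng(seed) -> np.random.Generator:
    if seed is None:
        raise ConfigError("a seed is mandatory for all generators")
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def simulate_yule_tree(n_tips: int, birth_rate: float = 1.0, seed=None) -> Phylogeny:
    """Ultrametric binary tree from a pure-birth (Yule) process.

    Starting from the root split (2 lineages), each of k extant lineages
    splits after Exponential(k * birth_rate) total waiting time; after the
    n-th lineage appears a final Exponential(n * birth_rate) interval runs to
    the present, so the expected root height is sum_{k=2..n} 1/(k * birth_rate).
    """
    if n_tips < 2:
        raise ConfigError(f"need n_tips >= 2, got {n_tips}")
    if birth_rate <= 0:
        raise ConfigError(f"birth_rate must be positive, got {birth_rate}")
    rng = _rng(seed)
    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    start = np.zeros(n_nodes)  # time the branch above each node begins
    lengths = np.zeros(n_nodes)
    root = n_tips  # internal ids n_tips .. n_nodes-1
    next_internal = n_tips + 1
    next_tip = 0
    t = 0.0
    # active branches: (parent node id, start time)
    active = [(root, 0.0), (root, 0.0)]
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        i = int(rng.integers(k))
        p, s = active.pop(i)
        v = next_internal
        next_internal += 1
        parent[v] = p
        lengths[v] = t - s
        start[v] = s
        active.append((v, t))
        active.append((v, t))
    t += rng.exponential(1.0 / (n_tips * birth_rate))
    for p, s in active:
        v = next_tip
        next_tip += 1
        parent[v] = p
        lengths[v] = t - s
    labels = [f"sp{i:04d}" for i in range(n_tips)]
    tree = Phylogeny(parent=parent, lengths=lengths, labels=labels,
                     n_tips=n_tips, root=root)
    tree.validate()
    return tree


def balanced_tree(n_tips: int, branch_length: float = 10.0) -> Phylogeny:
    """Fully symmetric ultrametric tree (n_tips a power of two), every branch
    of equal length.  Used as a maximally regular testbed — e.g. as the
    positive control for rate-shift detection, where every clade has a stem
    branch of known, non-negligible length."""
    levels = int(np.log2(n_tips))
    if 2 ** levels != n_tips or n_tips < 2:
        raise ConfigError(f"n_tips must be a power of two >= 2, got {n_tips}")
    if branch_length <= 0:
        raise ConfigError("branch_length must be positive")

    def newick(depth):
        if depth == 0:
            newick.i += 1
            return f"sp{newick.i - 1:04d}:{branch_length}"
        return f"({newick(depth - 1)},{newick(depth - 1)}):{branch_length}"

    newick.i = 0
    from .phylo_io import read_newick
    inner = f"({newick(levels - 1)},{newick(levels - 1)}):0;"
    return read_newick(inner)


def rescale_tree_depth(tree: Phylogeny, depth: float) -> Phylogeny:
    """Rescale all branch lengths so the maximum root-to-tip depth equals
    ``depth`` My (chronogram normalisation)."""
    if depth <= 0:
        raise ConfigError("depth must be positive")
    factor = depth / tree.total_depth()
    return Phylogeny(parent=tree.parent.copy(), lengths=tree.lengths * factor,
                     labels=list(tree.labels), n_tips=tree.n_tips, root=tree.root)


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def simulate_bm_traits(tree: Phylogeny, sigma2: float, root_state: float = 0.0,
                       lam: float = 1.0, rate_multipliers=None, seed=None):
    """Simulate one continuous trait under Brownian motion on the tree.

    Per-branch increments are Normal(0, sigma2 * multiplier * branch_length).
    ``rate_multipliers`` maps a node id to a positive factor applied to every
    branch inside that node's clade (the branches descending from the node;
    the node's own stem branch keeps the background rate, mirroring a rate
    shift occurring at the node itself).  ``lam`` < 1 first
    rescales the tree by the Pagel-lambda transformation, diluting shared
    history.  Returns ``(tip_values, node_states)`` with ``node_states`` over
    all nodes (true ancestral values, for recovery tests).
    """
    if sigma2 < 0:
        raise ConfigError("sigma2 must be non-negative")
    rng = _rng(seed)
    work = comparative.lambda_rescale(tree, lam)
    mult = np.ones(work.n_nodes)
    if rate_multipliers:
        for node, factor in rate_multipliers.items():
            node = int(node)
            if not 0 <= node < work.n_nodes:
                raise ConfigError(f"unknown clade node id {node} in rate_multipliers")
            if factor <= 0:
                raise ConfigError("rate multipliers must be positive")
            stack = list(work.children[node])
            while stack:
                v = stack.pop()
                mult[v] *= factor
                stack.extend(work.children[v])
    states = np.zeros(work.n_nodes)
    states[work.root] = root_state
    for v in work.preorder():
        p = work.parent[v]
        if p >= 0:
            sd = np.sqrt(sigma2 * mult[v] * work.lengths[v])
            states[v] = states[p] + rng.normal(0.0, sd)
    return states[: tree.n_tips].copy(), states


# ---------------------------------------------------------------------------
# landmark spirals
# ---------------------------------------------------------------------------

def generate_spiral_path(turns: float, base_radius: float = 2.0,
                         taper: float = 0.6, pitch: float = 0.8,
                         n_points: int = 86, noise_sd: float = 0.0,
                         seed=None):
    """Tapered-helix phantom of the basilar-membrane path.

    The curve is ``r(theta) = base_radius * (1 - taper * theta/theta_max)``
    winding ``turns`` revolutions while rising ``pitch`` mm per revolution,
    sampled at ``n_points`` approximately equal arc increments (the landmark
    protocol).  The true arc length is computed by dense numerical quadrature
    (1e5 segments) and returned as an oracle.

    Returns ``(LandmarkPath, true_arc_length, true_turns)``.
    """
    if turns <= 0:
        raise DomainError(f"turns must be positive, got {turns}")
    if n_points < 2:
        raise DomainError(f"need n_points >= 2, got {n_points}")
    if base_radius <= 0 or not 0.0 <= taper < 1.0 or pitch < 0:
        raise DomainError("invalid spiral geometry "
                          f"(base_radius={base_radius}, taper={taper}, pitch={pitch})")
    theta_max = 2.0 * np.pi * turns

    def xyz(theta):
        r = base_radius * (1.0 - taper * theta / theta_max)
        return np.column_stack([r * np.cos(theta), r * np.sin(theta),
                                pitch * theta / (2.0 * np.pi)])

    dense_t = np.linspace(0.0, theta_max, 100_001)
    dense = xyz(dense_t)
    seg = np.sqrt((np.diff(dense, axis=0) ** 2).sum(axis=1))
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    true_len = float(cum[-1])
    targets = np.linspace(0.0, true_len, n_points)
    theta_i = np.interp(targets, cum, dense_t)
    pts = xyz(theta_i)
    if noise_sd > 0:
        pts = pts + _rng(seed).normal(0.0, noise_sd, size=pts.shape)
    return LandmarkPath(pts, specimen_id="synthetic"), true_len, float(turns)


# ---------------------------------------------------------------------------
# joint study dataset
# ---------------------------------------------------------------------------

#: Generative audiogram curves used for synthetic calibration tables.
#: High-frequency limits (kHz) decline with log10 relative membrane length;
#: low-frequency limits decline with the product log10(membrane) * turns.
#: Chosen so a bat-ancestor-like cochlea (relative length ~4.4 mm/g^1/3,
#: 2.45 turns) hears up to ~100 kHz at 60 dB / ~60 kHz at 30 dB and down to
#: ~1 kHz — realistic for small laurasiatherians.  Synthetic, not fitted to
#: any published audiogram set.
SYNTHETIC_HEARING_CURVES = {
    "hf30": {"intercept": 2.78, "slope": -1.56},   # on log10 rel. membrane
    "hf60": {"intercept": 3.00, "slope": -1.56},
    "lf30": {"intercept": 1.18, "slope": -0.45},   # on log10(membrane) * turns
    "lf60": {"intercept": 1.08, "slope": -0.45},
}


@dataclass
class SimulationConfig:
    """Generative settings for :func:`generate_study_dataset`.

    Defaults are the study conditions: a 0.498/0.717 allometry of log10
    membrane length (mm) on log10 cube-root mass (g), an echolocator offset
    of +0.12 log10 units (~+32% membrane length), BM body mass with root at
    ~20 g, and turn counts following the cross-mammal relationship on
    relative membrane length.
    """

    n_species: int = 100
    birth_rate: float = 1.0
    tree_depth: float = 64.0            # My; chronogram normalisation
    # mass BM rate sized so tip log10-masses spread with sd ~1.5 over the tree
    # depth — a cross-mammal sample (grams to tonnes), as in comparative
    # allometries spanning shrews to large cetartiodactyls
    sigma2_mass: float = 0.036          # log10(g)^2 per My
    root_log_mass: float = 1.3          # ~20 g
    allometric_slope: float = 0.498
    allometric_intercept: float = 0.717
    echolocator_offset: float = 0.12    # log10 mm, added for echolocators
    sigma2_membrane_dev: float = 2.4e-6  # BM deviation around the allometry
    lam: float = 1.0                    # Pagel lambda applied to BM parts
    rate_multipliers: dict = field(default_factory=dict)  # group name -> factor
    noise_membrane: float = 0.02        # iid log10 noise around allometry
    turns_slope: float = 0.123          # log10 turns on log10 rel. membrane
    turns_intercept: float = 0.342
    noise_turns: float = 0.08
    call_model: str = "davies2013_phylo"
    noise_call: float = 0.05
    n_calibration: int = 38             # 14 bat-like + 24 other species
    noise_calibration: float = 0.05
    seed: int | None = None

    def validate(self) -> "SimulationConfig":
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if self.n_species < 4:
            raise ConfigError("n_species must be >= 4")
        positives = {
            "birth_rate": self.birth_rate, "tree_depth": self.tree_depth,
            "sigma2_mass": self.sigma2_mass,
        }
        for name, v in positives.items():
            if v <= 0:
                raise ConfigError(f"{name} must be positive, got {v}")
        for name, v in (("sigma2_membrane_dev", self.sigma2_membrane_dev),
                        ("noise_membrane", self.noise_membrane),
                        ("noise_turns", self.noise_turns),
                        ("noise_call", self.noise_call),
                        ("noise_calibration", self.noise_calibration)):
            if v < 0:
                raise ConfigError(f"{name} must be non-negative, got {v}")
        if not 0.0 <= self.lam <= 1.0:
            raise ConfigError(f"lam must be in [0, 1], got {self.lam}")
        for k, f in self.rate_multipliers.items():
            if k not in ("echolocators", "non-echolocators"):
                raise ConfigError(f"unknown rate-multiplier group {k!r}")
            if f <= 0:
                raise ConfigError("rate multipliers must be positive")
        if self.n_calibration < 4:
            raise ConfigError("n_calibration must be >= 4")
        return self


@dataclass
class StudyDataset:
    """A generated dataset plus every generative parameter (``truth``)."""

    tree: Phylogeny
    traits: pd.DataFrame
    calibration: pd.DataFrame
    truth: dict


def generate_study_dataset(config: SimulationConfig) -> StudyDataset:
    """Joint phylogeny + trait table + audiogram calibration table.

    The echolocator group is the root's child clade whose tip count is
    closest to half the species (a clade, so group and phylogeny are
    confounded exactly as in real data).  Membrane length follows the
    allometric line plus the group offset plus a BM deviation plus iid noise;
    turns follow the relative-membrane relationship; call frequencies follow
    the configured call-frequency model plus noise (echolocators only).
    """
    config.validate()
    rng = _rng(config.seed)
    seeds = rng.integers(0, 2 ** 31 - 1, size=8)
    tree = rescale_tree_depth(
        simulate_yule_tree(config.n_species, config.birth_rate, seed=int(seeds[0])),
        config.tree_depth)
    n = tree.n_tips

    # echolocator clade: root child closest to half the tips
    root_children = tree.children[tree.root]
    counts = [len(tree.clade_tips(c)) for c in root_children]
    echo_node = root_children[int(np.argmin([abs(c - n / 2) for c in counts]))]
    echo_tips = tree.clade_tips(echo_node)
    is_echo = np.zeros(n, dtype=bool)
    is_echo[echo_tips] = True

    mult = {}
    if "echolocators" in config.rate_multipliers:
        mult[echo_node] = config.rate_multipliers["echolocators"]

    log_mass, _ = simulate_bm_traits(tree, config.sigma2_mass,
                                     root_state=config.root_log_mass,
                                     lam=config.lam, seed=int(seeds[1]))
    mass = 10.0 ** log_mass
    dev, _ = simulate_bm_traits(tree, config.sigma2_membrane_dev,
                                lam=config.lam, rate_multipliers=mult,
                                seed=int(seeds[2]))
    x_allom = np.log10(mass ** (1.0 / 3.0))
    log_membrane = (config.allometric_intercept
                    + config.allometric_slope * x_allom
                    + config.echolocator_offset * is_echo
                    + dev
                    + rng.normal(0.0, config.noise_membrane, size=n))
    membrane = 10.0 ** log_membrane
    rel = np.array([relative_membrane_length(m, g) for m, g in zip(membrane, mass)])
    log_turns = (config.turns_intercept
                 + config.turns_slope * np.log10(rel)
                 + rng.normal(0.0, config.noise_turns, size=n))
    turns = np.round(10.0 ** log_turns * 4) / 4
    turns = np.clip(turns, 0.75, None)

    model = load_builtin_model(config.call_model)
    calls = {"call_min": np.full(n, np.nan), "call_peak": np.full(n, np.nan),
             "call_max": np.full(n, np.nan)}
    echo_idx = np.where(is_echo)[0]
    for key, par in zip(("call_min", "call_peak", "call_max"),
                        ("min", "peak", "max")):
        c = model.parameters[par]
        mu = (c["intercept"] + c["membrane"] * np.log10(membrane[echo_idx])
              + c["turns"] * np.log10(turns[echo_idx]))
        calls[key][echo_idx] = 10.0 ** (
            mu + rng.normal(0.0, config.noise_call, size=len(echo_idx)))
    echo_types = np.where(
        is_echo, rng.choice(["CF", "FM", "broadband"], size=n), "none")

    traits = pd.DataFrame({
        "species": tree.labels,
        "membrane_length": membrane,
        "turns": turns,
        "mass": mass,
        "echolocation_type": echo_types,
        **calls,
    })

    calibration = _generate_calibration(config, rng)

    truth = {
        "config": config,
        "echolocator_node": int(echo_node),
        "echolocator_species": [tree.labels[i] for i in echo_tips],
        "is_echolocator": is_echo,
        "log_mass": log_mass,
        "membrane_deviation": dev,
        "hearing_curves": SYNTHETIC_HEARING_CURVES,
    }
    return StudyDataset(tree=tree, traits=traits, calibration=calibration,
                        truth=truth)


def _generate_calibration(config: SimulationConfig, rng) -> pd.DataFrame:
    """Audiogram calibration table from the generative hearing curves."""
    m = config.n_calibration
    log_mass = rng.uniform(0.3, 3.3, size=m)           # 2 g .. 2 kg
    mass = 10.0 ** log_mass
    log_membrane = (config.allometric_intercept
                    + config.allometric_slope * log_mass / 3.0
                    + rng.normal(0.0, 0.05, size=m))
    membrane = 10.0 ** log_membrane
    rel = membrane / mass ** (1.0 / 3.0)
    turns = np.round((10.0 ** (config.turns_intercept
                               + config.turns_slope * np.log10(rel)
                               + rng.normal(0.0, config.noise_turns, size=m))) * 4) / 4
    turns = np.clip(turns, 0.75, None)
    cv = SYNTHETIC_HEARING_CURVES
    x_hi = np.log10(rel)
    x_lo = np.log10(membrane) * turns
    out = {"species": [f"cal{i:03d}" for i in range(m)],
           "membrane_length": membrane, "turns": turns, "mass": mass}
    for key, x in (("hf30", x_hi), ("hf60", x_hi), ("lf30", x_lo), ("lf60", x_lo)):
        mu = cv[key]["intercept"] + cv[key]["slope"] * x
        out[key] = 10.0 ** (mu + rng.normal(0.0, config.noise_calibration, size=m))
    return pd.DataFrame(out)
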