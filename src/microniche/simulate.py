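"""Synthetic-data generators with known ground truth.

Every downstream stage of the pipeline can be exercised against data whose
true structure is known: a community of strains with fixed carbon-source
niches and injected cooperative gains, node sets with a controlled shared
core, sequence alignments evolved on a known tree, inhibition labels drawn
from a known logistic model, logistic growth curves, and spent-media OD
tables with prescribed log-ratio effects.

The default community emulates the design of a 16-strain rhizosphere
synthetic community profiled on Biolog EcoPlates: 16 monocultures, 120
pairwise co-cultures, 31 carbon sources plus water blanks, three replicates
and readings on days 0, 4 and 7.
"""

from __future__ import annotations

import io as _io
import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Phylo

from .ecoplate import (
    COMMUNITY_ID,
    DAYS,
    PLATE_COLUMNS,
    REPLICATES,
    WATER,
    context_id,
    source_names,
)

#: Relative dye development at day 4 (day 7 == 1).  Only day 7 is used for
#: niche calls by default, so this shapes intermediate data without
#: affecting the default analysis.
DAY4_RAMP = 0.6

#: Basal absorbance of an uninoculated well (OD-595).
BASELINE = 0.08

#: Upper bound of the per-well day-0 offset (initial cell density plus
#: intrinsic substrate colour), removed by the day-0 subtraction.
DAY0_OFFSET_MAX = 0.05


# ---------------------------------------------------------------------------
# community truth + plate generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CommunityTruth:
    """Ground truth for a synthetic plate experiment.

    ``true_niche[i, s]`` says whether strain ``i`` grows on source ``s`` in
    monoculture.  ``pair_expansion`` holds cooperative gains injected at the
    pair level: a ``((i, j), s)`` entry (``i < j``) makes the co-culture grow
    on source ``s`` even though that is not implied by the monoculture
    niches.  Injected sources must lie outside the pair's shared niche.
    """

    n_strains: int
    n_sources: int
    true_niche: np.ndarray
    pair_expansion: frozenset = frozenset()
    signal_mean: float = 0.5
    blank_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strains <= 0 or self.n_sources <= 0:
            raise ValueError("strain and source counts must be positive")
        niche = np.asarray(self.true_niche)
        if niche.shape != (self.n_strains, self.n_sources):
            raise ValueError(
                f"true_niche shape {niche.shape} does not match "
                f"({self.n_strains}, {self.n_sources})"
            )
        if not np.isin(niche, (0, 1)).all():
            raise ValueError("true_niche entries must be 0/1")
        if self.signal_mean <= 0:
            raise ValueError("signal_mean must be positive")
        if self.blank_sd < 0:
            raise ValueError("blank_sd must be nonnegative")
        for (i, j), s in self.pair_expansion:
            if not (0 <= i < j < self.n_strains) or not 0 <= s < self.n_sources:
                raise ValueError(f"pair_expansion entry (({i},{j}),{s}) out of range")
            if niche[i, s] and niche[j, s]:
                raise ValueError(
                    f"injected expansion source {s} lies in the shared niche "
                    f"of pair ({i},{j})"
                )

    @property
    def strain_ids(self) -> tuple[str, ...]:
        return tuple(f"Q{i + 1}" for i in range(self.n_strains))

    @property
    def source_names(self) -> tuple[str, ...]:
        return source_names(self.n_sources)

    def pairs(self) -> list[tuple[int, int]]:
        return list(itertools.combinations(range(self.n_strains), 2))

    def pair_observed(self, i: int, j: int) -> set[int]:
        """Source indices the (i, j) co-culture grows on: the union of the
        members' niches plus any injected gains."""
        niche = np.asarray(self.true_niche)
        used = set(np.flatnonzero(niche[i] | niche[j]))
        used |= {s for (p, s) in self.pair_expansion if p == (i, j)}
        return used


def default_community_truth(
    seed: int = 0,
    n_strains: int = 16,
    n_sources: int = 31,
    use_prob: float = 0.45,
    expansion_pair_fraction: float = 0.5,
    expansion_mean_sources: float = 2.0,
    signal_mean: float = 0.5,
    blank_sd: float = 0.01,
) -> CommunityTruth:
    """Draw a community truth with realistic structure.

    Each strain uses each substrate independently with probability
    ``use_prob`` (at least one substrate per strain).  A fraction of pairs
    receives injected cooperative gains: 1 + Poisson(mean - 1) substrates
    drawn from those *neither* member uses alone, so the gains are genuine
    emergent niche expansion rather than complementation of one member.
    """
    rng = np.random.default_rng(seed)
    niche = (rng.random((n_strains, n_sources)) < use_prob).astype(np.int8)
    for i in range(n_strains):
        if niche[i].sum() == 0:
            niche[i, rng.integers(n_sources)] = 1
    gains = set()
    for i, j in itertools.combinations(range(n_strains), 2):
        if rng.random() >= expansion_pair_fraction:
            continue
        outside = np.flatnonzero((niche[i] | niche[j]) == 0)
        if outside.size == 0:
            continue
        k = 1 + rng.poisson(max(expansion_mean_sources - 1.0, 0.0))
        k = min(k, outside.size)
        for s in rng.choice(outside, size=k, replace=False):
            gains.add(((i, j), int(s)))
    return CommunityTruth(
        n_strains=n_strains,
        n_sources=n_sources,
        true_niche=niche,
        pair_expansion=frozenset(gains),
        signal_mean=signal_mean,
        blank_sd=blank_sd,
        seed=seed,
    )


def generate_plate_set(
    truth: CommunityTruth,
    include_community: bool = False,
    community_extra_sources: tuple[int, ...] = (),
) -> pd.DataFrame:
    """Long-format plate absorbance table for a community truth.

    One plate context per monoculture and per unordered pair (optionally the
    full community), each with all carbon sources plus water in triplicate
    on days 0, 4 and 7.  The absorbance model is::

        A = baseline + day0_offset(well) + ramp(day) * signal_mean * uses
            + Normal(0, blank_sd)

    where the day-0 offset is a fixed per-well nuisance (initial cells and
    substrate colour) present on every day, and water wells carry baseline
    plus noise only.  A co-culture uses a source iff either member does or
    the pair has an injected gain for it.  Negative absorbances can occur
    when noise is large relative to baseline.
    """
    rng = np.random.default_rng(truth.seed)
    niche = np.asarray(truth.true_niche)
    strains = truth.strain_ids
    sources = truth.source_names
    ramp = {0: 0.0, 4: DAY4_RAMP, 7: 1.0}

    contexts: list[tuple[str, str, set[int]]] = []
    for i, sid in enumerate(strains):
        contexts.append((sid, "", set(np.flatnonzero(niche[i]))))
    for i, j in truth.pairs():
        contexts.append((strains[i], strains[j], truth.pair_observed(i, j)))
    if include_community:
        used = set(np.flatnonzero(niche.any(axis=0)))
        used |= {int(s) for s in community_extra_sources}
        contexts.append((COMMUNITY_ID, "", used))

    rows = []
    for culture, partner, used in contexts:
        for s, name in enumerate(sources):
            for rep in REPLICATES:
                offset = rng.uniform(0.0, DAY0_OFFSET_MAX)
                for day in DAYS:
                    signal = truth.signal_mean * ramp[day] if s in used else 0.0
                    noise = rng.normal(0.0, truth.blank_sd) if truth.blank_sd else 0.0
                    rows.append(
                        (culture, partner, name, rep, day,
                         BASELINE + offset + signal + noise)
                    )
        for rep in REPLICATES:
            for day in DAYS:
                noise = rng.normal(0.0, truth.blank_sd) if truth.blank_sd else 0.0
                rows.append((culture, partner, WATER, rep, day, BASELINE + noise))
    return pd.DataFrame(rows, columns=list(PLATE_COLUMNS))


def truth_niche_frame(truth: CommunityTruth) -> pd.DataFrame:
    """True binary niche calls per culture context (monocultures + pairs),
    as a wide frame matching the output of plate scoring."""
    sources = truth.source_names
    strains = truth.strain_ids
    niche = np.asarray(truth.true_niche)
    data = {}
    for i, sid in enumerate(strains):
        data[sid] = niche[i].astype(int)
    for i, j in truth.pairs():
        ctx = context_id(strains[i], strains[j])
        row = np.zeros(truth.n_sources, dtype=int)
        row[sorted(truth.pair_observed(i, j))] = 1
        data[ctx] = row
    frame = pd.DataFrame.from_dict(data, orient="index", columns=list(sources))
    frame.index.name = "culture"
    return frame


# ---------------------------------------------------------------------------
# metabolic node sets
# ---------------------------------------------------------------------------

def generate_node_sets(
    n_strains: int,
    universe: int,
    overlap_level: float,
    seed: int = 0,
    set_size: int = 40,
) -> dict[str, set[str]]:
    """Per-strain metabolite-node sets with a controlled shared core.

    Every strain receives ``set_size`` nodes: a core of
    ``round(overlap_level * set_size)`` nodes shared by all strains plus
    strain-private nodes, all drawn without replacement from a universe of
    ``universe`` node ids.  ``overlap_level=1`` gives identical sets
    (functional distance 0 for every pair); ``overlap_level=0`` gives
    pairwise disjoint sets (distance 1).
    """
    if not 0.0 <= overlap_level <= 1.0:
        raise ValueError("overlap_level must lie in [0, 1]")
    if n_strains <= 0 or set_size <= 0:
        raise ValueError("n_strains and set_size must be positive")
    core_size = round(overlap_level * set_size)
    private = set_size - core_size
    needed = core_size + n_strains * private
    if universe < needed:
        raise ValueError(
            f"universe of {universe} nodes cannot host a shared core of "
            f"{core_size} plus {n_strains} disjoint private sets of {private}"
        )
    rng = np.random.default_rng(seed)
    draw = rng.choice(universe, size=needed, replace=False)
    names = [f"M{k:05d}" for k in draw]
    core = set(names[:core_size])
    sets = {}
    for i in range(n_strains):
        lo = core_size + i * private
        sets[f"Q{i + 1}"] = core | set(names[lo:lo + private])
    return sets


def generate_node_sets_varied(
    n_strains: int,
    universe: int = 400,
    seed: int = 0,
    size_range: tuple[int, int] = (60, 140),
) -> dict[str, set[str]]:
    """Node sets with heterogeneous sizes and pair-varying overlap.

    Each strain draws a set of uniform random size from a shared universe
    with strain-specific node preferences (half the universe is "common"
    and favoured 3:1), so pairwise functional distances spread over a range
    instead of collapsing to a single value as in the controlled-core
    generator.
    """
    if size_range[0] < 1 or size_range[1] > universe:
        raise ValueError("set sizes must fit inside the universe")
    rng = np.random.default_rng(seed)
    names = np.array([f"M{k:05d}" for k in range(universe)])
    weights = np.where(np.arange(universe) < universe // 2, 3.0, 1.0)
    weights /= weights.sum()
    sets = {}
    for i in range(n_strains):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        chosen = rng.choice(universe, size=size, replace=False, p=weights)
        sets[f"Q{i + 1}"] = set(names[chosen])
    return sets


# ---------------------------------------------------------------------------
# sequence alignments on a tree
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def generate_alignment(
    tree_newick: str,
    seq_length: int,
    subst_rate: float = 1.0,
    seed: int = 0,
) -> dict[str, str]:
    """Evolve a gapless alignment along a tree under an equal-rate
    four-letter substitution process (Jukes-Cantor).

    Branch lengths times ``subst_rate`` give expected substitutions per
    site; along a branch of scaled length v each site changes with
    probability (3/4)(1 - exp(-4v/3)), landing uniformly on the other three
    bases.  The root sequence is drawn from the uniform stationary
    distribution.
    """
    if seq_length <= 0:
        raise ValueError("seq_length must be positive")
    if subst_rate < 0:
        raise ValueError("subst_rate must be nonnegative")
    try:
        tree = Phylo.read(_io.StringIO(tree_newick), "newick")
    except Exception as exc:  # malformed newick
        raise ValueError(f"malformed newick tree: {exc}") from exc
    rng = np.random.default_rng(seed)
    root_seq = rng.integers(0, 4, size=seq_length)

    out: dict[str, str] = {}

    def descend(clade, seq) -> None:
        for child in clade.clades:
            v = (child.branch_length or 0.0) * subst_rate
            p_change = 0.75 * (1.0 - math.exp(-4.0 * v / 3.0))
            child_seq = seq.copy()
            hit = rng.random(seq_length) < p_change
            n_hit = int(hit.sum())
            if n_hit:
                # uniform over the three other bases
                child_seq[hit] = (child_seq[hit] + rng.integers(1, 4, size=n_hit)) % 4
            if child.clades:
                descend(child, child_seq)
            else:
                name = child.name or f"taxon_{len(out) + 1}"
                out[name] = "".join(_BASES[child_seq])

    if not tree.root.clades:  # single-leaf "tree"
        raise ValueError("tree must have at least two leaves")
    descend(tree.root, root_seq)
    return out


# ---------------------------------------------------------------------------
# inhibition assay
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InhibitionTruth:
    """Logistic ground truth for pairwise inhibition.

    The probability that an unordered pair is antagonistic at distance d is
    logit^-1(beta0 + beta1 * d).
    """

    beta0: float
    beta1: float
    distances: dict = field(default_factory=dict)  # (a, b) sorted -> d >= 0

    def __post_init__(self) -> None:
        for pair, d in self.distances.items():
            if d < 0:
                raise ValueError(f"distance for pair {pair} is negative")
            if tuple(sorted(pair)) != tuple(pair):
                raise ValueError(f"pair {pair} must be sorted (unordered pair key)")

    def probability(self, d: float) -> float:
        return 1.0 / (1.0 + math.exp(-(self.beta0 + self.beta1 * d)))


def generate_inhibition(
    truth: InhibitionTruth,
    seed: int = 0,
    resource_level: str = "high",
    include_self_controls: bool = True,
) -> pd.DataFrame:
    """Long-format halo records for one resource level.

    Pair labels are Bernoulli draws from the truth's logistic model.  An
    antagonistic pair is realised as one of the directed patterns
    (x=1, y=0), (x=0, y=1) or (x=1, y=1) with equal probability, matching
    the convention that a pair is antagonistic if either direction shows a
    clearance halo.  Self pairs are emitted as halo-0 controls.
    """
    rng = np.random.default_rng(seed)
    rows = []
    strains = sorted({s for pair in truth.distances for s in pair})
    for (a, b), d in sorted(truth.distances.items()):
        label = rng.random() < truth.probability(d)
        if label:
            x, y = [(1, 0), (0, 1), (1, 1)][rng.integers(3)]
        else:
            x, y = 0, 0
        rows.append((a, b, resource_level, x))
        rows.append((b, a, resource_level, y))
    if include_self_controls:
        for s in strains:
            rows.append((s, s, resource_level, 0))
    return pd.DataFrame(rows, columns=["focal", "target", "resource_level", "halo"])


# ---------------------------------------------------------------------------
# growth curves + supernatant
# ---------------------------------------------------------------------------

def logistic_curve(t: np.ndarray, K: float, r: float, N0: float) -> np.ndarray:
    """Logistic growth N(t) = K / (1 + ((K - N0)/N0) exp(-r t))."""
    t = np.asarray(t, dtype=float)
    return K / (1.0 + ((K - N0) / N0) * np.exp(-r * t))


def generate_growth_curves(
    K: float,
    r: float,
    N0: float,
    noise_sd: float,
    t_grid: np.ndarray,
    seed: int = 0,
    n_replicates: int = 1,
) -> pd.DataFrame:
    """Noisy logistic OD time series (columns: time_h, od, replicate)."""
    if not (K > N0 > 0):
        raise ValueError("need K > N0 > 0")
    if r <= 0:
        raise ValueError("growth rate must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    t = np.asarray(t_grid, dtype=float)
    frames = []
    for rep in range(1, n_replicates + 1):
        od = logistic_curve(t, K, r, N0)
        if noise_sd:
            od = od + rng.normal(0.0, noise_sd, size=t.size)
        frames.append(pd.DataFrame({"time_h": t, "od": od, "replicate": rep}))
    return pd.concat(frames, ignore_index=True)


def default_supernatant_effects(
    strains: tuple[str, ...],
    seed: int = 0,
    high_mean: float = 0.15,
    high_sd: float = 0.25,
    low_mean: float = -0.5,
    low_sd: float = 0.2,
) -> pd.DataFrame:
    """True log10 spent/fresh effects for the full grower x donor grid.

    Defaults emulate the study conditions: under high resource availability
    spent media frequently still support growth (the positive fraction of a
    Normal(0.15, 0.25) is about 0.73), while under low availability growth
    in spent media is almost always suppressed.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for grower in strains:
        for donor in strains:
            rows.append((grower, donor, "high", rng.normal(high_mean, high_sd)))
            rows.append((grower, donor, "low", rng.normal(low_mean, low_sd)))
    return pd.DataFrame(rows, columns=["grower", "donor", "resource_level", "effect"])


def generate_supernatant(
    effects: pd.DataFrame,
    rep_sd: float = 0.02,
    seed: int = 0,
    fresh_od: float = 0.5,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Spent-vs-fresh OD table from per-case log10-ratio effects.

    For each case (grower, donor, resource level) and replicate,
    OD_spent = OD_fresh * 10^(effect + Normal(0, rep_sd)).
    """
    if fresh_od <= 0:
        raise ValueError("fresh OD must be positive")
    if rep_sd < 0:
        raise ValueError("rep_sd must be nonnegative")
    required = {"grower", "donor", "resource_level", "effect"}
    if not required.issubset(effects.columns):
        raise ValueError(f"effects table needs columns {sorted(required)}")
    rng = np.random.default_rng(seed)
    rows = []
    for rec in effects.itertuples(index=False):
        for rep in range(1, n_replicates + 1):
            noise = rng.normal(0.0, rep_sd) if rep_sd else 0.0
            od_spent = fresh_od * 10.0 ** (rec.effect + noise)
            rows.append(
                (rec.grower, rec.donor, rec.resource_level, rep, od_spent, fresh_od)
            )
    return pd.DataFrame(
        rows,
        columns=["grower", "donor", "resource_level", "replicate",
                 "od_spent", "od_fresh"],
    )
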