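"""Synthetic communities with known assembly processes.

This module generates the ground truth that the inference stages are
tested against.  A lognormal metacommunity plays the role of the regional
species pool; local communities of N individuals are then assembled under
one of five regimes — pure drift, homogeneous or variable selection, and
dispersal limitation or homogenizing dispersal — using a Wright–Fisher
style resampling model with immigration.  A field-design wrapper lays
replicated scenarios onto a compartment x week x treatment grid with a
per-week community-size schedule, emulating a season-long, replicated
drought trial on a single crop host.

Selection acts through a single quantitative trait.  When traits are
simulated by Brownian motion along the cladogram they carry phylogenetic
signal, so selection produces the phylogenetic clustering that the
beta-nearest-taxon statistics are designed to detect.

All randomness flows from one integer seed through
``numpy.random.SeedSequence``; every design cell derives a child seed
deterministically, so any subset of the grid reproduces without
simulating the rest.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .datamodel import (
    RANKS,
    CommunityTable,
    SampleMetadata,
    TableMode,
    TaxonAnnotation,
    patristic_distances,
    taxonomy_to_cladogram,
)

__all__ = [
    "AssemblyProcess",
    "Metacommunity",
    "AssemblyScenario",
    "FieldDesign",
    "random_taxonomy",
    "sample_metacommunity",
    "simulate_assembly",
    "simulate_field_design",
    "simulate_succession",
    "sorghum_design",
]


#: span of the quantitative niche axis traits are scaled to
NICHE_AXIS_RANGE = 1.5


class AssemblyProcess(str, enum.Enum):
    drift = "drift"
    homogeneous_selection = "homogeneous_selection"
    variable_selection = "variable_selection"
    dispersal_limitation = "dispersal_limitation"
    homogenizing_dispersal = "homogenizing_dispersal"


@dataclass
class Metacommunity:
    """Regional species pool: relative abundances, optional traits, tree."""

    taxon_ids: list[str]
    abundances: np.ndarray
    traits: np.ndarray | None = None
    tree: TreeNode | None = None
    annotation: TaxonAnnotation | None = None

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        if (self.abundances < 0).any():
            raise ValueError("metacommunity abundances must be non-negative")
        total = self.abundances.sum()
        if not np.isclose(total, 1.0, atol=1e-12):
            raise ValueError("metacommunity abundances must sum to 1")
        if len(self.taxon_ids) != self.abundances.size:
            raise ValueError("taxon_ids and abundances differ in length")

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)


@dataclass
class AssemblyScenario:
    """Parameters of one local-assembly regime.

    N is the number of individuals per local community; m the per-
    generation immigration (or, for homogenizing dispersal, exchange)
    rate; s the strength of Gaussian stabilizing selection on the trait.
    """

    process: AssemblyProcess = AssemblyProcess.drift
    N: int = 50
    generations: int = 50
    m: float = 0.1
    s: float = 0.0
    #: shared trait optimum for homogeneous selection; None anchors it at
    #: the trait of the taxon at the 95th trait percentile — an occupied,
    #: tail phenotype whose neighbourhood is clade-restricted, so
    #: selection yields phylogenetic clustering
    optimum: float | None = None
    plot_optima: Mapping[str, float] | None = None
    #: fraction of the pool each replicate is seeded from under dispersal limitation
    seeding_fraction: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        self.process = AssemblyProcess(self.process)
        if self.N < 1:
            raise ValueError("local community size N must be >= 1")
        if self.generations < 0:
            raise ValueError("generations must be non-negative")
        if not (0.0 <= self.m <= 1.0):
            raise ValueError("immigration rate m must lie in [0, 1]")
        if self.s < 0:
            raise ValueError("selection strength s must be >= 0")
        if not (0.0 < self.seeding_fraction <= 1.0):
            raise ValueError("seeding_fraction must lie in (0, 1]")


@dataclass
class FieldDesign:
    """Replicated compartment x week x treatment grid of scenarios.

    ``scenarios`` maps (compartment, week, treatment) cells to an
    :class:`AssemblyScenario`; ``size_schedule`` maps week to local
    community size N, overriding the scenario's N so a community-size
    gradient can be laid across the season.
    """

    compartments: Sequence[str]
    weeks: Sequence[int]
    treatments: Sequence[str]
    replicates: int
    base_scenario: AssemblyScenario
    scenarios: Mapping[tuple[str, int, str], AssemblyScenario] | None = None
    size_schedule: Mapping[int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not (self.compartments and list(self.weeks) != [] and self.treatments):
            raise ValueError("empty design")

    def cells(self) -> list[tuple[str, int, str]]:
        return [
            (c, int(w), t)
            for c in self.compartments
            for w in self.weeks
            for t in self.treatments
        ]

    def scenario_for(self, cell: tuple[str, int, str]) -> AssemblyScenario:
        sc = self.base_scenario
        if self.scenarios and cell in self.scenarios:
            sc = self.scenarios[cell]
        if self.size_schedule is not None:
            import dataclasses

            sc = dataclasses.replace(sc, N=int(self.size_schedule[cell[1]]))
        return sc


# ---------------------------------------------------------------------------
# metacommunity
# ---------------------------------------------------------------------------

#: per-rank (min, max) subgroup counts for phylum..genus; deep ranks split
#: more than shallow ones, giving family-sized groups of close relatives
#: the way fungal OTU taxonomies do
DEFAULT_SPLIT_PROFILE: tuple[tuple[int, int], ...] = (
    (3, 4),  # phyla per kingdom
    (2, 3),  # classes per phylum
    (2, 3),  # orders per class
    (1, 2),  # families per order
    (1, 2),  # genera per family
)


def random_taxonomy(
    taxon_ids: Sequence[str],
    rng: np.random.Generator,
    split_profile: Sequence[tuple[int, int]] = DEFAULT_SPLIT_PROFILE,
) -> TaxonAnnotation:
    """Random nested lineage assignment producing a realistic cladogram.

    All taxa share one kingdom; at each deeper rank every existing group
    splits into a random number of subgroups drawn from the per-rank
    range of ``split_profile``.
    """
    n = len(taxon_ids)
    labels = {"kingdom": ["Fungi"] * n}
    groups = np.zeros(n, dtype=int)
    counter = 0
    for rank, (lo, hi) in zip(RANKS[1:], split_profile):
        new = np.empty(n, dtype=int)
        for g in np.unique(groups):
            members = np.flatnonzero(groups == g)
            k = int(rng.integers(lo, hi + 1))
            sub = rng.integers(0, k, size=members.size)
            for j, s in zip(members, sub):
                new[j] = counter + int(s)
            counter += k
        groups = new
        labels[rank] = [f"{rank[0]}{g}" for g in groups]
    guilds = rng.choice(
        ["saprotroph", "plant_pathogen", "amf", "endophyte", "yeast"], size=n
    )
    df = pd.DataFrame({**labels, "guild": guilds}, index=pd.Index(taxon_ids, name="taxon_id"))
    return TaxonAnnotation(df)


def _brownian_traits(
    tree: TreeNode,
    rng: np.random.Generator,
    sigma: float = 1.0,
    depth_decay: float = 0.5,
) -> dict[str, float]:
    """Brownian motion along the tree with depth-decaying step variance.

    Steps on branches ``d`` edges below the root get standard deviation
    ``sigma * sqrt(length) * depth_decay**d``, concentrating trait
    divergence at deep splits.  This encodes niche conservatism — the
    assumption underlying nearest-taxon phylogenetic inference — so that
    taxa sharing a phenotype band are close relatives, not converged
    strangers.
    """
    values: dict[int, float] = {id(tree): 0.0}
    depth: dict[int, int] = {id(tree): 0}
    out: dict[str, float] = {}
    for node in tree.preorder(include_self=False):
        d = depth[id(node.parent)]
        depth[id(node)] = d + 1
        step = rng.normal(0.0, sigma * np.sqrt(node.length or 0.0) * depth_decay**d)
        values[id(node)] = values[id(node.parent)] + step
        if node.is_tip():
            out[node.name] = values[id(node)]
    return out


def sample_metacommunity(
    S: int,
    lognormal_sigma: float = 1.0,
    trait_model: str = "brownian_on_tree",
    seed: int | np.random.SeedSequence = 0,
) -> Metacommunity:
    """Draw a lognormal species-abundance pool of S taxa.

    Lineages are assigned by random nested splitting, the cladogram is
    built from them, and (for ``brownian_on_tree``) a quantitative trait
    diffuses along that tree so that related taxa have similar trait
    values.  ``independent`` draws i.i.d. normal traits instead, which
    removes the phylogenetic signal from any downstream selection.
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    if lognormal_sigma <= 0:
        raise ValueError("lognormal_sigma must be positive")
    if trait_model not in ("brownian_on_tree", "independent"):
        raise ValueError(f"unknown trait_model {trait_model!r}")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    taxon_ids = [f"OTU{i + 1:04d}" for i in range(S)]
    ab = rng.lognormal(mean=0.0, sigma=lognormal_sigma, size=S)
    ab = ab / ab.sum()
    annot = random_taxonomy(taxon_ids, rng)
    tree = taxonomy_to_cladogram(annot)
    if trait_model == "brownian_on_tree":
        tip_traits = _brownian_traits(tree, rng)
        traits = np.array([tip_traits[t] for t in taxon_ids])
    else:
        traits = rng.normal(size=S)
    # fixed-range niche axis: at the reference selection strength s = 100
    # the Gaussian kernel width 1/sqrt(2 s) ~ 0.07 covers ~5% of the axis,
    # about one family-level clade under the default taxonomy
    if S > 1 and np.ptp(traits) > 0:
        traits = (traits - traits.min()) / np.ptp(traits) * NICHE_AXIS_RANGE
    return Metacommunity(taxon_ids, ab, traits=traits, tree=tree, annotation=annot)


# ---------------------------------------------------------------------------
# local assembly
# ---------------------------------------------------------------------------

def _selection_weights(meta: Metacommunity, s: float, optimum: float) -> np.ndarray:
    if meta.traits is None:
        raise ValueError("selection scenario requires metacommunity traits")
    return np.exp(-s * (meta.traits - optimum) ** 2)


def simulate_assembly(
    meta: Metacommunity,
    scenario: AssemblyScenario,
    n_replicates: int,
    sample_ids: Sequence[str] | None = None,
    rng: np.random.Generator | None = None,
) -> CommunityTable:
    """Assemble ``n_replicates`` local communities under one regime.

    Each community holds exactly N individuals.  Per generation the N
    individuals are resampled multinomially from a mixture of the local
    frequencies and an immigration source, with selection entering as a
    Gaussian trait-matching multiplier on the resampling weights:

    * drift: source = (1-m) local + m metacommunity, no selection.
    * homogeneous_selection: same source, one shared trait optimum.
    * variable_selection: per-plot optima (``scenario.plot_optima``
      keyed by replicate id, or drawn from the trait range when absent).
    * dispersal_limitation: each replicate is seeded from a distinct
      random subset of the pool, then drifts with m = 0.
    * homogenizing_dispersal: immigration source is the current mean
      frequency across replicates (migrant exchange at rate m).

    With ``generations = 0`` every replicate is a single multinomial
    draw of N individuals from the metacommunity.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(scenario.seed if scenario.seed is not None else 0)
        )
    S = meta.n_taxa
    N = scenario.N
    proc = scenario.process
    if sample_ids is None:
        sample_ids = [f"rep{i + 1:02d}" for i in range(n_replicates)]
    if len(sample_ids) != n_replicates:
        raise ValueError("sample_ids length must equal n_replicates")

    # per-replicate selection weights (uniform when no selection)
    if proc in (AssemblyProcess.homogeneous_selection, AssemblyProcess.variable_selection):
        if meta.traits is None:
            raise ValueError("selection scenario requires metacommunity traits")
        if proc is AssemblyProcess.homogeneous_selection:
            if scenario.optimum is None:
                optimum = float(np.quantile(meta.traits, 0.95, method="nearest"))
            else:
                optimum = float(scenario.optimum)
            optima = [optimum] * n_replicates
        else:
            if scenario.plot_optima:
                keys = list(scenario.plot_optima)
                optima = [
                    float(scenario.plot_optima[keys[i % len(keys)]])
                    for i in range(n_replicates)
                ]
            else:
                lo, hi = float(meta.traits.min()), float(meta.traits.max())
                optima = list(rng.uniform(lo, hi, size=n_replicates))
        weights = np.stack([_selection_weights(meta, scenario.s, o) for o in optima])
    else:
        weights = np.ones((n_replicates, S))

    # initial communities
    counts = np.empty((n_replicates, S), dtype=np.int64)
    if proc is AssemblyProcess.dispersal_limitation:
        k = max(1, int(round(scenario.seeding_fraction * S)))
        for r in range(n_replicates):
            subset = rng.choice(S, size=k, replace=False)
            p = np.zeros(S)
            p[subset] = meta.abundances[subset]
            if p.sum() == 0:
                p[subset] = 1.0
            counts[r] = rng.multinomial(N, p / p.sum())
    else:
        for r in range(n_replicates):
            counts[r] = rng.multinomial(N, meta.abundances)

    m = 0.0 if proc is AssemblyProcess.dispersal_limitation else scenario.m
    for _ in range(scenario.generations):
        freqs = counts / N
        if proc is AssemblyProcess.homogenizing_dispersal:
            source = freqs.mean(axis=0)
        else:
            source = meta.abundances
        p = (1.0 - m) * freqs + m * source
        p = p * weights
        rowsum = p.sum(axis=1, keepdims=True)
        # a replicate whose weighted frequencies vanish restarts from the source
        dead = rowsum[:, 0] <= 0
        if dead.any():
            p[dead] = np.maximum(source * weights[dead], 1e-300)
            rowsum = p.sum(axis=1, keepdims=True)
        p = p / rowsum
        for r in range(n_replicates):
            counts[r] = rng.multinomial(N, p[r])

    df = pd.DataFrame(
        counts.astype(float),
        index=pd.Index([str(s) for s in sample_ids], name="sample_id"),
        columns=meta.taxon_ids,
    )
    return CommunityTable(df, TableMode.counts)


# ---------------------------------------------------------------------------
# field design
# ---------------------------------------------------------------------------

def simulate_field_design(
    design: FieldDesign,
    meta: Metacommunity,
) -> tuple[CommunityTable, SampleMetadata]:
    """One sample per (compartment, week, treatment, replicate) cell.

    Every cell gets a deterministic child seed spawned from the design
    seed, so identical seeds give byte-identical output and any single
    cell can be re-simulated in isolation.
    """
    cells = design.cells()
    if not cells:
        raise ValueError("empty design")
    root_ss = np.random.SeedSequence(design.seed)
    children = root_ss.spawn(len(cells))

    tables = []
    meta_rows = []
    for (cell, child) in zip(cells, children):
        compartment, week, treatment = cell
        scenario = design.scenario_for(cell)
        rng = np.random.default_rng(child)
        ids = [
            f"{compartment}_w{week:02d}_{treatment}_r{i + 1:02d}"
            for i in range(design.replicates)
        ]
        tab = simulate_assembly(meta, scenario, design.replicates, sample_ids=ids, rng=rng)
        tables.append(tab.data)
        for i, sid in enumerate(ids):
            meta_rows.append(
                {
                    "sample_id": sid,
                    "compartment": compartment,
                    "week": week,
                    "treatment": treatment,
                    "plot": f"plot{i + 1:02d}",
                    "community_size": float(scenario.N),
                }
            )
    table = CommunityTable(pd.concat(tables, axis=0), TableMode.counts)
    metadata = SampleMetadata(pd.DataFrame(meta_rows))
    return table, metadata.aligned_to(table)


def sorghum_design(
    base_scenario: AssemblyScenario | None = None,
    replicates: int = 6,
    seed: int = 0,
) -> FieldDesign:
    """The season-long trial layout: 4 compartments x 17 weeks x 3
    treatments x 6 replicates.  The drought weeks that go unsampled in
    the trial are handled by :func:`simulate_sorghum_season`; this
    factory gives the dense grid for quick experiments.
    """
    if base_scenario is None:
        base_scenario = AssemblyScenario()
    return FieldDesign(
        compartments=["leaf", "root", "rhizosphere", "soil"],
        weeks=list(range(1, 18)),
        treatments=["control", "pre_flowering_drought", "post_flowering_drought"],
        replicates=replicates,
        base_scenario=base_scenario,
        seed=seed,
    )


def simulate_sorghum_season(
    meta: Metacommunity,
    base_scenario: AssemblyScenario | None = None,
    replicates: int = 6,
    size_schedule: Mapping[int, int] | None = None,
    seed: int = 0,
) -> tuple[CommunityTable, SampleMetadata]:
    """Simulate the full trial, skipping the unsampled drought weeks.

    Pre-flowering drought is sampled from week 3 and post-flowering
    drought from week 8; week 0 contributes soil-only samples from the
    18 field plots.  With 6 replicates this yields 1026 samples.  The
    default size schedule grows the community tenfold over the season
    (small early communities, large late ones).
    """
    if base_scenario is None:
        base_scenario = AssemblyScenario()
    if size_schedule is None:
        size_schedule = {w: int(round(30 * 10 ** (w / 17))) for w in range(0, 18)}

    # control: all 17 weeks; pre-flowering from week 3; post-flowering from week 8
    spans = {
        "control": range(1, 18),
        "pre_flowering_drought": range(3, 18),
        "post_flowering_drought": range(8, 18),
    }
    parts: list[tuple[CommunityTable, SampleMetadata]] = []
    root_ss = np.random.SeedSequence(seed)
    child_seeds = root_ss.spawn(len(spans) + 1)
    for (treatment, weeks), child in zip(spans.items(), child_seeds[:-1]):
        design = FieldDesign(
            compartments=["leaf", "root", "rhizosphere", "soil"],
            weeks=list(weeks),
            treatments=[treatment],
            replicates=replicates,
            base_scenario=base_scenario,
            size_schedule=size_schedule,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        parts.append(simulate_field_design(design, meta))
    # week-0 pre-planting soil, one core per field plot (18 plots)
    design0 = FieldDesign(
        compartments=["soil"],
        weeks=[0],
        treatments=["control"],
        replicates=18,
        base_scenario=base_scenario,
        size_schedule=size_schedule,
        seed=int(child_seeds[-1].generate_state(1)[0] % (2**31)),
    )
    parts.append(simulate_field_design(design0, meta))

    table = CommunityTable(
        pd.concat([t.data for t, _ in parts], axis=0), TableMode.counts
    )
    metadata = SampleMetadata(pd.concat([m.data for _, m in parts], axis=0))
    return table, metadata.aligned_to(table)


# ---------------------------------------------------------------------------
# successional gradient (for community-age modelling)
# ---------------------------------------------------------------------------

def simulate_succession(
    S: int = 150,
    weeks: Sequence[int] = tuple(range(1, 18)),
    replicates: int = 6,
    depth: int = 500,
    niche_width: float = 2.5,
    seed: int = 0,
    sampling_seed: int | None = None,
    week_offset: float = 0.0,
    sample_prefix: str = "",
) -> tuple[CommunityTable, SampleMetadata]:
    """Monotone taxon turnover along a weekly time axis.

    Each taxon gets a Gaussian temporal niche (peak week uniform across
    the season); a sample at week w draws ``depth`` individuals from the
    niche-weighted pool.  Because the community slides predictably along
    the axis, sampling age is recoverable from composition — the ground
    truth for the community-age regression protocol.

    ``seed`` fixes the niche structure (taxon peaks and base abundances);
    ``sampling_seed`` (default: same as seed) fixes the count noise, so
    two calls sharing ``seed`` describe the same successional system.
    ``week_offset`` shifts the *composition* relative to the recorded
    week label — a developmentally delayed treatment is a negative
    offset.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    taxon_ids = [f"OTU{i + 1:04d}" for i in range(S)]
    # peaks span the fixed 0..17 season (plus margins) regardless of the
    # weeks sampled, so calls sharing `seed` share the niche structure
    peak = rng.uniform(-2.0, 19.0, size=S)
    base = rng.lognormal(0.0, 1.0, size=S)
    rng = np.random.default_rng(
        np.random.SeedSequence(seed if sampling_seed is None else sampling_seed)
    )
    rows = []
    meta_rows = []
    for w_label in weeks:
        w = w_label + week_offset
        p = base * np.exp(-((w - peak) ** 2) / (2 * niche_width**2))
        p = p / p.sum()
        for r in range(replicates):
            sid = f"{sample_prefix}w{w_label:02d}_r{r + 1:02d}"
            rows.append(pd.Series(rng.multinomial(depth, p).astype(float), index=taxon_ids, name=sid))
            meta_rows.append(
                {
                    "sample_id": sid,
                    "compartment": "root",
                    "week": int(w_label),
                    "treatment": "control",
                    "community_size": float(depth),
                }
            )
    df = pd.DataFrame(rows)
    df.index.name = "sample_id"
    table = CommunityTable(df, TableMode.counts)
    metadata = SampleMetadata(pd.DataFrame(meta_rows))
    return table, metadata.aligned_to(table)
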