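"""Synthetic-data generators with known ground truth.

Three generators feed the pipeline so every stage can be exercised and
calibrated without downloads:

* ``simulate_family`` evolves a fixed-length protein family along a dated
  (ultrametric) species tree under a 20-state Poisson substitution process,
  optionally rerouting one lineage through a horizontal (HGT) or
  endosymbiotic (EGT) transfer event at a stated time.  Under the equal-
  exchangeability model the expected fraction of differing sites between two
  sequences separated by ``d`` expected substitutions/site is
  ``(19/20) * (1 - exp(-(20/19) d))``, which the tests hold the generator to.
* ``simulate_genome_with_island`` draws an i.i.d. host genome and inserts a
  compositionally distinct island at a known position (truth coordinates are
  0-based half-open).
* ``simulate_clocklike_tree`` draws a coalescent-style ultrametric topology
  and converts node ages to branch lengths at a given substitution rate,
  with optional multiplicative Gaussian noise, for clock-dating recovery
  tests.

All generators are deterministic per seed.  There is no indel model: family
sequences keep a constant length, so simulated families double as trivially
"aligned" inputs.  EGT is modeled exactly like HGT (a transfer at the
recipient clade's stem); only the scenario label differs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import dendropy
import numpy as np

from .scoring import AMINO_ACIDS, ProteinSequence
from .kmerscan import NucleotideSequence

__all__ = [
    "SpeciesTreeSpec",
    "Scenario",
    "FamilySim",
    "GenomeSim",
    "ClockTreeSim",
    "simulate_family",
    "simulate_genome_with_island",
    "simulate_clocklike_tree",
    "expected_p_distance",
]

_N_STATES = 20


def expected_p_distance(d: float) -> float:
    """Expected differing-site fraction at ``d`` expected substitutions/site."""
    return (19 / 20) * (1 - np.exp(-(20 / 19) * d))


@dataclass
class SpeciesTreeSpec:
    """Ultrametric species tree (Newick, branch lengths in My) with rates.

    ``rate`` is the default substitution rate (subs/site/My); ``rates`` may
    override it per lineage, keyed by the label of the node subtending the
    edge (leaf label or internal node label).
    """

    newick: str
    rate: float
    rates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rate < 0 or any(r < 0 for r in self.rates.values()):
            raise ValueError("substitution rates must be non-negative")
        self.tree = dendropy.Tree.get(
            data=self.newick, schema="newick",
            suppress_internal_node_taxa=False,
        )
        # node ages from tip-side accumulation; tree must be ultrametric
        ages: dict[dendropy.Node, float] = {}
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                ages[node] = 0.0
            else:
                child_ages = []
                for ch in node.child_nodes():
                    if ch.edge.length is None:
                        raise ValueError("species tree edges need durations (My)")
                    child_ages.append(ages[ch] + ch.edge.length)
                if max(child_ages) - min(child_ages) > 1e-6 * max(child_ages, default=1):
                    raise ValueError("species tree is not ultrametric")
                ages[node] = child_ages[0]
        self.ages = ages

    def node(self, label: str) -> dendropy.Node:
        for node in self.tree.preorder_node_iter():
            if node.taxon is not None and node.taxon.label == label:
                return node
            if node.label == label:
                return node
        raise KeyError(f"no node labelled {label!r} in the species tree")

    def edge_rate(self, node: dendropy.Node) -> float:
        label = node.taxon.label if node.taxon is not None else node.label
        return self.rates.get(label, self.rate) if label else self.rate

    def taxa(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]


@dataclass(frozen=True)
class Scenario:
    """Vertical descent or a dated transfer from donor to recipient lineage."""

    mode: str                        # 'vertical' | 'hgt' | 'egt'
    donor: str | None = None         # label of the node below the donor edge
    recipient: str | None = None
    transfer_time: float | None = None   # Ma

    def __post_init__(self) -> None:
        if self.mode not in ("vertical", "hgt", "egt"):
            raise ValueError("mode must be vertical, hgt or egt")
        if self.mode != "vertical":
            if None in (self.donor, self.recipient, self.transfer_time):
                raise ValueError(f"{self.mode} scenarios need donor, recipient "
                                 "and transfer_time")


@dataclass
class FamilySim:
    sequences: dict[str, ProteinSequence]
    scenario: Scenario
    tree: SpeciesTreeSpec
    root_sequence: str
    seed: int


@dataclass
class GenomeSim:
    genome: NucleotideSequence
    island_start: int      # 0-based inclusive; start == end when no island
    island_end: int        # exclusive
    host_freqs: tuple[float, ...]
    island_freqs: tuple[float, ...]
    seed: int


def _evolve(seq: np.ndarray, d: float, rng: np.random.Generator) -> np.ndarray:
    """One branch of the 20-state Poisson process, ``d`` expected subs/site.

    A site with at least one event (rate (20/19)d, events resample the state
    uniformly over all 20 amino acids) ends in a uniform state; this is the
    exact transition distribution, applied site-wise.
    """
    if d < 0:
        raise ValueError("branch length must be non-negative")
    p_hit = 1.0 - np.exp(-(_N_STATES / (_N_STATES - 1)) * d)
    hit = rng.random(seq.size) < p_hit
    out = seq.copy()
    out[hit] = rng.integers(0, _N_STATES, int(hit.sum()))
    return out


def _decode(states: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[s] for s in states)


def _edge_span(spec: SpeciesTreeSpec, node: dendropy.Node) -> tuple[float, float]:
    if node.parent_node is None:
        raise ValueError("the root has no subtending edge")
    return spec.ages[node], spec.ages[node.parent_node]


def simulate_family(
    tree: SpeciesTreeSpec,
    scenario: Scenario,
    length: int,
    seed: int,
) -> FamilySim:
    """Evolve one protein family along the species tree under a scenario.

    The root sequence is uniform over the 20 amino acids.  For hgt/egt the
    recipient lineage's sequence is replaced, at ``transfer_time``, by the
    donor lineage's sequence at that moment, and evolves onward inside the
    recipient's subtree.
    """
    if length < 50:
        raise ValueError("family length must be >= 50")
    rng = np.random.default_rng(seed)
    root_states = rng.integers(0, _N_STATES, length)

    donor_node = recipient_node = None
    T = None
    if scenario.mode != "vertical":
        donor_node = tree.node(scenario.donor)
        recipient_node = tree.node(scenario.recipient)
        T = float(scenario.transfer_time)
        for name, node in (("donor", donor_node), ("recipient", recipient_node)):
            lo, hi = _edge_span(tree, node)
            if not (lo <= T <= hi):
                raise ValueError(
                    f"transfer_time {T} outside the {name} edge span [{lo}, {hi}]"
                )
        if donor_node is recipient_node:
            raise ValueError("donor and recipient lineages must differ")
        anc = donor_node
        while anc is not None:
            if anc is recipient_node:
                raise ValueError("donor lineage lies inside the recipient subtree")
            anc = anc.parent_node

    states: dict[dendropy.Node, np.ndarray] = {}
    donor_at_T: list[np.ndarray | None] = [None]

    def descend(node: dendropy.Node, parent_states: np.ndarray,
                skip_recipient: bool) -> None:
        for child in node.child_nodes():
            if skip_recipient and child is recipient_node:
                continue
            d_my = child.edge.length
            rate = tree.edge_rate(child)
            if child is donor_node and T is not None:
                hi = tree.ages[node]
                upper = _evolve(parent_states, rate * (hi - T), rng)
                donor_at_T[0] = upper
                states[child] = _evolve(upper, rate * (T - tree.ages[child]), rng)
            else:
                states[child] = _evolve(parent_states, rate * d_my, rng)
            descend(child, states[child], skip_recipient)

    root = tree.tree.seed_node
    states[root] = root_states
    if scenario.mode == "vertical":
        descend(root, root_states, skip_recipient=False)
    else:
        # phase 1: everything except the recipient subtree (fixes donor_at_T)
        descend(root, root_states, skip_recipient=True)
        assert donor_at_T[0] is not None
        rate = tree.edge_rate(recipient_node)
        states[recipient_node] = _evolve(
            donor_at_T[0], rate * (T - tree.ages[recipient_node]), rng
        )
        descend(recipient_node, states[recipient_node], skip_recipient=False)

    sequences = {
        leaf.taxon.label: ProteinSequence(leaf.taxon.label, _decode(states[leaf]))
        for leaf in tree.tree.leaf_node_iter()
    }
    return FamilySim(sequences, scenario, tree, _decode(root_states), seed)


def simulate_genome_with_island(
    host_len: int,
    host_freqs,
    island_len: int,
    island_freqs,
    position: int,
    seed: int,
    genome_id: str = "sim_genome",
) -> GenomeSim:
    """i.i.d. host genome with a compositionally distinct island inserted."""
    host_freqs = tuple(float(f) for f in host_freqs)
    island_freqs = tuple(float(f) for f in island_freqs)
    for f in (host_freqs, island_freqs):
        if len(f) != 4 or any(x < 0 for x in f):
            raise ValueError("base frequencies must be 4 non-negative numbers")
        if abs(sum(f) - 1.0) > 1e-9:
            raise ValueError("base frequencies must sum to 1")
    if not (0 <= position <= host_len):
        raise ValueError("island position outside the host genome")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    host = rng.choice(bases, size=host_len, p=host_freqs)
    island = rng.choice(bases, size=island_len, p=island_freqs)
    genome = "".join(host[:position]) + "".join(island) + "".join(host[position:])
    end = position + island_len if island_len else position
    return GenomeSim(NucleotideSequence(genome_id, genome),
                     position, end, host_freqs, island_freqs, seed)


@dataclass
class ClockTreeSim:
    """A clock-like tree with its generating truth."""

    tree: dendropy.Tree          # branch lengths in expected subs/site
    true_root_age: float
    true_rate: float
    noise_sd: float
    node_ages: dict[frozenset[str], float]   # clade (leaf set) -> true age, Ma
    seed: int

    def clade_age(self, taxa) -> float:
        return self.node_ages[frozenset(taxa)]


def simulate_clocklike_tree(
    n_taxa: int,
    root_age: float,
    rate: float,
    noise_sd: float,
    seed: int,
) -> ClockTreeSim:
    """Random coalescent-style ultrametric tree rendered in substitutions.

    Node ages come from cumulative exponential waiting times rescaled so the
    deepest node sits at ``root_age``; each branch length is
    ``rate * duration * (1 + N(0, noise_sd))`` truncated at zero.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    if root_age <= 0 or rate <= 0 or noise_sd < 0:
        raise ValueError("root_age and rate must be positive, noise_sd >= 0")
    rng = np.random.default_rng(seed)

    waits = rng.exponential(1.0, n_taxa - 1)
    ages = np.cumsum(waits) / waits.sum() * root_age
    ages[-1] = root_age   # pin the root exactly against cumsum rounding

    taxa = [f"t{i+1}" for i in range(n_taxa)]
    tns = dendropy.TaxonNamespace(taxa)
    tree = dendropy.Tree(taxon_namespace=tns)
    lineages: list[tuple[dendropy.Node, float]] = []
    for label in taxa:
        node = dendropy.Node(taxon=tns.get_taxon(label))
        lineages.append((node, 0.0))

    node_ages: dict[frozenset[str], float] = {}
    leafsets: dict[dendropy.Node, frozenset[str]] = {
        node: frozenset([node.taxon.label]) for node, _ in lineages
    }
    for age in ages:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        (a, age_a), (b, age_b) = lineages[i], lineages[j]
        parent = dendropy.Node()
        for child, child_age in ((a, age_a), (b, age_b)):
            parent.add_child(child)
            duration = age - child_age
            noise = 1.0 + rng.normal(0.0, noise_sd) if noise_sd > 0 else 1.0
            child.edge.length = max(0.0, rate * duration * noise)
        leafsets[parent] = leafsets[a] | leafsets[b]
        node_ages[leafsets[parent]] = float(age)
        lineages = [x for k, x in enumerate(lineages) if k not in (i, j)]
        lineages.append((parent, float(age)))

    tree.seed_node = lineages[0][0]
    tree.is_rooted = True
    return ClockTreeSim(tree, float(root_age), rate, noise_sd, node_ages, seed)
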