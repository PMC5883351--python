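"""Synthetic plastome-style data with known species structure.

The generator mirrors the generative assumption of the PTP likelihood:
a Yule topology over species, a random coalescent topology within each
species, and per-edge branch lengths drawn from two exponential regimes —
``Exp(lambda_sp)`` for speciation edges (every edge down to and including
a species MRCA's stem) and ``Exp(lambda_coal)`` for coalescent edges
(strictly inside a species). Sequences evolve site-independently under
Jukes-Cantor along the resulting tree, with optional rate hotspots that
produce SNP-dense windows like the variable intergenic spacers of real
plastomes.

Default regimes: speciation edges average 0.02 substitutions/site and
within-species edges 0.0004 (rate ratio 50), matching the shallow
interspecific and very low intraspecific plastome divergence the pipeline
is designed for.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from .errors import ConfigurationError, RegionError
from .markers import MarkerRegion
from .msa_io import Alignment

__all__ = [
    "SimulationTruth",
    "simulate_tree",
    "simulate_alignment",
    "end_to_end_fixture",
    "PROFILES",
]

DEFAULT_LAMBDA_SP = 50.0
DEFAULT_LAMBDA_COAL = 2500.0


@dataclass
class SimulationTruth:
    """Ground truth of one simulation replicate."""

    tree: dendropy.Tree  # gene tree; edges annotated with .regime
    species_map: dict  # accession -> species
    lambda_sp: float
    lambda_coal: float
    hotspots: tuple = ()  # (start, end, multiplier), 1-based inclusive
    seed: int = 0
    sister_pairs: tuple = ()  # ((speciesA, speciesB), ...) barely diverged

    @property
    def true_entities(self) -> tuple[frozenset, ...]:
        """The true delimitation: one entity per species."""
        by_species: dict = {}
        for acc, sp in self.species_map.items():
            by_species.setdefault(sp, set()).add(acc)
        return tuple(
            frozenset(v)
            for _, v in sorted(by_species.items())
        )


def _yule_topology(labels: list, rng: np.random.Generator) -> dendropy.Node:
    """Random sequential-join topology; returns the root (lengths unset)."""
    nodes = [dendropy.Node(label=lab) for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    return nodes[0]


def simulate_tree(
    n_species: int,
    tips_per_species: int | tuple[int, int] = 4,
    lambda_sp: float = DEFAULT_LAMBDA_SP,
    lambda_coal: float = DEFAULT_LAMBDA_COAL,
    seed: int = 0,
    forced_sister_pairs: int = 0,
) -> SimulationTruth:
    """Simulate a species tree plus within-species subtrees.

    ``tips_per_species`` is either a fixed count or an inclusive (lo, hi)
    range sampled per species. ``forced_sister_pairs`` makes that many
    species pairs sisters with coalescent-scale stems, i.e. barely
    diverged — the hard case for delimitation.
    """
    if n_species < 1:
        raise ConfigurationError(f"n_species must be >= 1, got {n_species}")
    if lambda_sp <= 0 or lambda_coal <= 0:
        raise ConfigurationError("rates lambda_sp/lambda_coal must be > 0")
    if 2 * forced_sister_pairs > n_species:
        raise ConfigurationError("too many forced sister pairs")
    rng = np.random.default_rng(seed)
    species = [f"sp{i + 1:02d}" for i in range(n_species)]

    # species-level topology, with forced sister pairs pre-joined
    sister_pairs = []
    units: list = []
    k = 0
    for p in range(forced_sister_pairs):
        a, b = species[k], species[k + 1]
        k += 2
        pair = dendropy.Node()
        na, nb = dendropy.Node(label=a), dendropy.Node(label=b)
        pair.add_child(na)
        pair.add_child(nb)
        pair.label = None
        sister_pairs.append((a, b))
        units.append(pair)
    units.extend(dendropy.Node(label=s) for s in species[k:])
    if len(units) > 1:
        nodes = units[:]
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            parent = dendropy.Node()
            parent.add_child(nodes[i])
            parent.add_child(nodes[j])
            nodes = [n for q, n in enumerate(nodes) if q not in (i, j)]
            nodes.append(parent)
        sp_root = nodes[0]
    else:
        sp_root = units[0]

    shrunk_stems = {s for pair in sister_pairs for s in pair}
    species_map: dict = {}
    taxa: list[str] = []

    # replace each species leaf by a coalescent subtree over its accessions
    tns = dendropy.TaxonNamespace()
    for leaf in list(_leaves(sp_root)):
        sp = leaf.label
        if isinstance(tips_per_species, tuple):
            lo, hi = tips_per_species
            m = int(rng.integers(lo, hi + 1))
        else:
            m = int(tips_per_species)
        accs = [f"{sp}_a{i + 1}" for i in range(m)]
        for a in accs:
            species_map[a] = sp
        taxa.extend(accs)
        if m == 1:
            leaf.label = accs[0]
            continue
        sub_root = _yule_topology(accs, rng)
        leaf.label = None
        for ch in sub_root.child_nodes():
            sub_root.remove_child(ch)
            leaf.add_child(ch)
        leaf._species_mrca = sp  # noqa: SLF001 - internal marker

    # assign taxa, regimes and branch lengths
    for t in taxa:
        tns.new_taxon(label=t)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=sp_root)
    tree.is_rooted = True
    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            nd.taxon = tns.get_taxon(nd.label)
            nd.label = None

    def species_of_subtree(nd) -> str | None:
        sps = {species_map[l.taxon.label] for l in nd.leaf_iter()}
        return next(iter(sps)) if len(sps) == 1 else None

    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        sp_here = species_of_subtree(nd)
        parent_sp = species_of_subtree(nd.parent_node)
        if sp_here is not None and parent_sp == sp_here:
            regime = "coalescent"  # strictly inside a species subtree
        else:
            regime = "speciation"
        scale = 1.0 / lambda_coal if regime == "coalescent" else 1.0 / lambda_sp
        if (
            regime == "speciation"
            and sp_here is not None
            and sp_here in shrunk_stems
        ):
            # stem of a forced sister-pair member: coalescent-scale length
            scale = 1.0 / lambda_coal
        nd.edge.length = float(rng.exponential(scale))
        nd.edge.regime = regime
    return SimulationTruth(
        tree=tree,
        species_map=species_map,
        lambda_sp=lambda_sp,
        lambda_coal=lambda_coal,
        seed=seed,
        sister_pairs=tuple(sister_pairs),
    )


def _leaves(root: dendropy.Node):
    stack = [root]
    while stack:
        nd = stack.pop()
        kids = nd.child_nodes()
        if not kids:
            yield nd
        else:
            stack.extend(kids)


def simulate_alignment(
    truth: SimulationTruth,
    length: int,
    base_rate: float = 1.0,
    hotspots: Sequence[tuple[int, int, float]] = (),
    seed: int | None = None,
) -> tuple[Alignment, list[MarkerRegion]]:
    """Evolve an alignment along the gene tree under Jukes-Cantor.

    Each column's expected substitutions along an edge of length b are
    ``b * base_rate * m`` where m is the hotspot multiplier covering the
    column (1 elsewhere). Returns the alignment and the hotspot regions as
    1-based marker regions named HS1, HS2, ...
    """
    if length < 1:
        raise ConfigurationError(f"length must be >= 1, got {length}")
    if base_rate < 0:
        raise ConfigurationError("base_rate must be >= 0")
    mult = np.ones(length)
    covered = np.zeros(length, dtype=bool)
    regions = []
    for i, (start, end, m) in enumerate(hotspots):
        if not (1 <= start <= end <= length):
            raise RegionError(f"hotspot ({start},{end}) outside [1,{length}]")
        if m <= 0:
            raise RegionError("hotspot multiplier must be > 0")
        sl = slice(start - 1, end)
        if covered[sl].any():
            raise RegionError("overlapping hotspots")
        covered[sl] = True
        mult[sl] = m
        regions.append(MarkerRegion(f"HS{i + 1}", start, end, source="auto"))
    rng = np.random.default_rng(truth.seed if seed is None else seed)

    tree = truth.tree
    seqs: dict = {}
    root_seq = rng.integers(0, 4, size=length)
    seqs[id(tree.seed_node)] = root_seq
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        parent = seqs[id(nd.parent_node)]
        d = (nd.edge.length or 0.0) * base_rate * mult
        p_change = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
        hit = rng.random(length) < p_change
        child = parent.copy()
        if hit.any():
            offs = rng.integers(1, 4, size=int(hit.sum()))
            child[hit] = (child[hit] + offs) % 4
        seqs[id(nd)] = child
        if not nd.is_leaf():
            continue
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    taxa = []
    rows = []
    for leaf in tree.leaf_node_iter():
        taxa.append(leaf.taxon.label)
        rows.append(bases[seqs[id(leaf)]].tobytes().decode("ascii"))
    truth.hotspots = tuple((r.start, r.end, float(m)) for r, (_, _, m) in zip(regions, hotspots))
    return Alignment(tuple(taxa), tuple(rows)), regions


#: Named study conditions for end-to-end runs.
PROFILES = {
    # clean species: within/between rate ratio 50
    "easy": dict(
        n_species=5,
        tips_per_species=4,
        lambda_sp=DEFAULT_LAMBDA_SP,
        lambda_coal=DEFAULT_LAMBDA_COAL,
        forced_sister_pairs=0,
        length=20_000,
        base_rate=1.0,
        hotspots=((8001, 8800, 20.0),),
    ),
    # ratio 5 with two barely diverged sister pairs
    "hard": dict(
        n_species=6,
        tips_per_species=3,
        lambda_sp=50.0,
        lambda_coal=250.0,
        forced_sister_pairs=2,
        length=20_000,
        base_rate=1.0,
        hotspots=((8001, 8800, 20.0),),
    ),
    # single exponential regime: no species structure beyond one
    "null": dict(
        n_species=1,
        tips_per_species=20,
        lambda_sp=50.0,
        lambda_coal=50.0,
        forced_sister_pairs=0,
        length=20_000,
        base_rate=1.0,
        hotspots=(),
    ),
}


def end_to_end_fixture(
    profile: str, seed: int = 0
) -> tuple[Alignment, dict, SimulationTruth]:
    """Alignment + species map + truth for a named study condition."""
    if profile not in PROFILES:
        raise ConfigurationError(
            f"unknown profile {profile!r}; choose from {sorted(PROFILES)}"
        )
    cfg = PROFILES[profile]
    truth = simulate_tree(
        n_species=cfg["n_species"],
        tips_per_species=cfg["tips_per_species"],
        lambda_sp=cfg["lambda_sp"],
        lambda_coal=cfg["lambda_coal"],
        seed=seed,
        forced_sister_pairs=cfg["forced_sister_pairs"],
    )
    aln, _ = simulate_alignment(
        truth,
        length=cfg["length"],
        base_rate=cfg["base_rate"],
        hotspots=cfg["hotspots"],
        seed=seed + 1_000_003,
    )
    return aln, dict(truth.species_map), truth


def write_truth(truth: SimulationTruth, path: str | Path) -> None:
    """JSON dump of the ground truth (tree written separately as Newick)."""
    payload = {
        "species_map": truth.species_map,
        "lambda_sp": truth.lambda_sp,
        "lambda_coal": truth.lambda_coal,
        "hotspots": list(truth.hotspots),
        "seed": truth.seed,
        "sister_pairs": [list(p) for p in truth.sister_pairs],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
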