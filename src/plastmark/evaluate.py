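"""Marker scoring: species-discrimination success and the marker report.

A species is *successfully identified* by a delimitation when some
delimited entity's tip set equals that species' accession set exactly —
the species is recovered monophyletic and exclusive, neither lumped with
another species nor split across entities. A looser criterion ("not
split": all accessions fall in a single entity, lumping tolerated) is
available behind a flag.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .delimit import Delimitation, McmcResult, mcmc_delimitation, ml_delimitation
from .errors import LabelError, PlastmarkError
from .markers import MarkerRegion, extract_region
from .msa_io import Alignment, concatenate
from .snpscan import percent_variable_sites
from .trees import (
    midpoint_root,
    neighbor_joining,
    pairwise_distance,
    prune_taxa,
    root_with_outgroup,
)

__all__ = ["EngineConfig", "species_discrimination", "evaluate_markers", "delimit_alignment"]


@dataclass(frozen=True)
class EngineConfig:
    """Knobs for the tree-building + delimitation engine.

    ``mcmc_steps=0`` skips MCMC (no ASV column); ``outgroup`` taxa are
    used for rooting and then pruned before delimitation, otherwise the
    tree is midpoint-rooted.
    """

    distance_model: str = "p"
    model: str = "multi"
    alpha: float = 0.01
    mcmc_steps: int = 10_000
    chains: int = 2
    burnin: float = 0.10
    seed: int = 0
    outgroup: tuple[str, ...] = ()
    criterion: str = "exact"  # {"exact", "not_split"}


def species_discrimination(
    delim: Delimitation,
    species_map: Mapping[str, str],
    criterion: str = "exact",
) -> tuple[int, float]:
    """Count species whose accession set is recovered by the delimitation.

    Returns ``(n_identified, fraction)`` over the species present among the
    delimitation's tips.
    """
    tips = set().union(*delim.entities) if delim.entities else set()
    unmapped = [t for t in tips if t not in species_map]
    if unmapped:
        raise LabelError(f"tips missing from species map: {sorted(unmapped)}")
    by_species: dict = {}
    for acc in tips:
        by_species.setdefault(species_map[acc], set()).add(acc)
    entity_sets = [frozenset(e) for e in delim.entities]
    entity_of = {acc: i for i, e in enumerate(entity_sets) for acc in e}
    n_ident = 0
    for accs in by_species.values():
        accs = frozenset(accs)
        if criterion == "exact":
            ok = accs in entity_sets
        elif criterion == "not_split":
            ok = len({entity_of[a] for a in accs}) == 1
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
        n_ident += bool(ok)
    n_species = len(by_species)
    return n_ident, (n_ident / n_species if n_species else 0.0)


def _trivial_delimitation(taxa, model: str) -> Delimitation:
    """Single-entity result for data with no measurable divergence."""
    return Delimitation(
        species_roots=(frozenset(taxa),),
        loglik=float("nan"),
        model=model,
        lambda_sp=None,
        lambda_coal=(None,),
        null_loglik=float("nan"),
        lrt_stat=0.0,
        lrt_df=0,
        p_value=1.0,
    )


def delimit_alignment(
    aln: Alignment, cfg: EngineConfig, seed: int | None = None
) -> tuple[Delimitation, McmcResult | None]:
    """Distance tree -> rooting -> (optional outgroup pruning) -> PTP.

    An alignment with no measurable divergence (all pairwise distances
    zero) carries no delimitation signal and returns the single-entity
    result directly.
    """
    dm = pairwise_distance(aln, cfg.distance_model)
    if dm.matrix.max() <= 0.0:
        keep = [t for t in aln.taxa if t not in set(cfg.outgroup)]
        return _trivial_delimitation(keep, cfg.model), None
    tree = neighbor_joining(dm)
    if cfg.outgroup:
        tree = root_with_outgroup(tree, cfg.outgroup)
        tree = prune_taxa(tree, cfg.outgroup)
        tree.is_rooted = True
    else:
        tree = midpoint_root(tree)
    run_seed = cfg.seed if seed is None else seed
    ml = ml_delimitation(tree, model=cfg.model, alpha=cfg.alpha)
    mc = None
    if cfg.mcmc_steps > 0:
        mc = mcmc_delimitation(
            tree,
            steps=cfg.mcmc_steps,
            chains=cfg.chains,
            burnin=cfg.burnin,
            seed=run_seed,
            model=cfg.model,
            alpha=cfg.alpha,
        )
    return ml, mc


def _marker_seed(base_seed: int, name: str) -> int:
    h = hashlib.sha256(f"{base_seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def evaluate_markers(
    aln: Alignment,
    regions: Sequence[MarkerRegion],
    species_map: Mapping[str, str],
    combos: Sequence[Sequence[str]] = (),
    cfg: EngineConfig = EngineConfig(),
) -> pd.DataFrame:
    """Score each marker region and each concatenated combination.

    For every marker (and combo): extract the sub-alignment, build an NJ
    tree, root it, run ML (+ optional MCMC) PTP delimitation, and report
    percent variable sites, species identified and ASV. Deterministic
    given ``cfg.seed``. Stage errors are re-raised tagged with the marker
    name.
    """
    by_name = {r.name: r for r in regions}
    for combo in combos:
        unknown = [n for n in combo if n not in by_name]
        if unknown:
            raise LabelError(f"combo references unknown regions: {unknown}")
    rows = []
    jobs: list[tuple[str, Alignment]] = [
        (r.name, extract_region(aln, r)) for r in regions
    ]
    for combo in combos:
        name = "+".join(combo)
        sub = concatenate(
            [extract_region(aln, by_name[n]) for n in combo], names=list(combo)
        )
        jobs.append((name, sub))
    for name, sub in jobs:
        try:
            ml, mc = delimit_alignment(sub, cfg, seed=_marker_seed(cfg.seed, name))
            n_ident, frac = species_discrimination(
                ml, species_map, criterion=cfg.criterion
            )
            rows.append(
                {
                    "marker": name,
                    "length": sub.length,
                    "percent_variable_sites": percent_variable_sites(sub),
                    "n_entities": ml.n_entities,
                    "n_species_identified": n_ident,
                    "percent_species_identified": 100.0 * frac,
                    "asv": (mc.asv if mc is not None else np.nan),
                    "p_value": ml.p_value,
                }
            )
        except PlastmarkError as exc:
            raise type(exc)(f"marker {name!r}: {exc}") from exc
    return pd.DataFrame(rows)


def write_report(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
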