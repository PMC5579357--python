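"""Dollo-parsimony reconstruction of gene-content histories.

Dollo parsimony allows a character (here: possession of a gene) to be gained
exactly once and lost any number of times.  For a presence/absence profile on
a rooted species tree the maximum-parsimony history is then fully determined:
the gene originated at the last common ancestor of all present species, and
each maximal subtree below that origin containing no present species is one
loss event (counted per pruned branch).  A gene whose origin is the tree root
is called ancestral to the whole panel (present in the last common ancestor,
e.g. LECA for a pan-eukaryotic panel).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np

from .profiles import PhyloProfile
from .tree import SpeciesTree


@dataclass
class DolloReconstruction:
    protein_name: str
    origin: frozenset[str]  # clade (leaf-code set) of the gain node
    losses: tuple[frozenset[str], ...]  # clades of the pruned branches
    leca: bool  # origin == tree root

    @property
    def loss_count(self) -> int:
        return len(self.losses)

    def replay(self) -> frozenset[str]:
        """Leaf set implied by gain-at-origin followed by the loss prunings."""
        present = set(self.origin)
        for clade in self.losses:
            present -= clade
        return frozenset(present)


def dollo_reconstruct(profile: PhyloProfile, tree: SpeciesTree) -> DolloReconstruction:
    """Single-gain / minimal-loss history of ``profile`` on ``tree``.

    Raises on an all-absent profile (no origin is definable) and on a
    catalog/tree leaf-set mismatch.
    """
    if set(profile.codes) != set(tree.leaf_codes):
        raise ValueError(
            f"profile {profile.protein_name!r}: catalog does not match tree leaves"
        )
    present = profile.present_codes
    if not present:
        raise ValueError(
            f"profile {profile.protein_name!r} is all-absent; Dollo origin undefined"
        )
    origin = tree.mrca(present)
    losses: list[frozenset[str]] = []

    def walk(node) -> None:
        for child in tree.children(node):
            clade = tree.clade(child)
            if clade.isdisjoint(present):
                losses.append(clade)  # maximal absent subtree: one loss
            else:
                walk(child)

    walk(origin)
    return DolloReconstruction(
        protein_name=profile.protein_name,
        origin=tree.clade(origin),
        losses=tuple(losses),
        leca=(origin is tree.root),
    )


def brute_force_min_losses(
    profile: PhyloProfile, tree: SpeciesTree
) -> tuple[frozenset[str], int]:
    """Exhaustive-search oracle for the minimal single-gain history.

    Enumerates every candidate gain node and, for each, every subset of
    branches below it in order of increasing size, until a loss set is found
    whose replay reproduces the observed profile.  Only feasible on small
    trees (<= 12 leaves).
    """
    if len(tree) > 12:
        raise ValueError("brute force limited to trees with <= 12 leaves")
    present = profile.present_codes
    if not present:
        raise ValueError("all-absent profile has no history")
    candidates = [
        node for node in tree.nodes() if present <= tree.clade(node)
    ]
    best: tuple[int, int, frozenset[str]] | None = None  # (losses, clade size, clade)
    for gain in candidates:
        gain_clade = tree.clade(gain)
        below = [
            tree.clade(n)
            for n in tree.nodes()
            if tree.clade(n) < gain_clade
        ]
        found = None
        for size in range(len(below) + 1):
            for combo in combinations(below, size):
                leaves = set(gain_clade)
                for clade in combo:
                    leaves -= clade
                if leaves == present:
                    found = size
                    break
            if found is not None:
                break
        if found is not None:
            key = (found, len(gain_clade), gain_clade)
            if best is None or key[:2] < best[:2]:
                best = key
    assert best is not None  # gain at MRCA always admits a solution
    return best[2], best[0]


def transitions(profile: PhyloProfile, order: Sequence[str] | None = None) -> int:
    """Number of adjacent present/absent state changes along the profile.

    Species order defaults to the profile's catalog order; pass a tree-derived
    leaf order to make adjacency reflect relatedness.
    """
    pres = profile.presence
    if order is not None:
        idx = {c: i for i, c in enumerate(profile.codes)}
        pres = pres[[idx[c] for c in order]]
    return int(np.sum(pres[1:] != pres[:-1]))


def mean_loss_count(
    reconstructions: Iterable[DolloReconstruction],
    subset: Iterable[str] | None = None,
    *,
    leca_only: bool = True,
) -> float:
    """Mean number of losses over a protein subset.

    By default restricted to proteins whose origin is the tree root
    (ancestral proteins), matching how post-ancestor loss frequencies are
    normally summarized.
    """
    recs = list(reconstructions)
    if subset is not None:
        wanted = set(subset)
        known = {r.protein_name for r in recs}
        missing = wanted - known
        if missing:
            raise KeyError(f"unknown proteins in subset: {sorted(missing)}")
        recs = [r for r in recs if r.protein_name in wanted]
    if leca_only:
        recs = [r for r in recs if r.leca]
    if not recs:
        raise ValueError("no reconstructions left after filtering")
    return float(np.mean([r.loss_count for r in recs]))


def dollo_report(
    reconstructions: Iterable[DolloReconstruction],
    profiles: Mapping[str, PhyloProfile] | None = None,
    order: Sequence[str] | None = None,
):
    """Tabular summary: protein, origin size, loss count, ancestral flag, transitions."""
    import pandas as pd

    rows = []
    for rec in reconstructions:
        row = {
            "protein": rec.protein_name,
            "origin_clade_size": len(rec.origin),
            "loss_count": rec.loss_count,
            "leca": rec.leca,
        }
        if profiles is not None:
            row["transitions"] = transitions(profiles[rec.protein_name], order)
        rows.append(row)
    return pd.DataFrame(rows).set_index("protein")
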