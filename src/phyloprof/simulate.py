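"""Synthetic gene-content histories with ground truth.

Generates the data the analysis assumes: a rooted species tree, genes that
originate once and are lost stochastically per branch (loss is inherited —
the generative counterpart of Dollo parsimony), pairs of genes with coupled
loss events (co-evolving complex subunits), a multifunctional gene retained
iff at least one of two partners is present, and orthogroup FASTA fixtures
with a motif planted conditional on a partner's presence.  Every simulation
is a pure function of (tree, config, seed).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .profiles import PhyloProfile
from .tree import SpeciesTree

_MAX_RESAMPLES = 100
# canonical MIM instance planted into motif-carrier fixture sequences
PLANTED_MOTIF = "KILAAAAP"
_MOTIF_OFFSET = 40
# background alphabet excludes proline so a canonical MIM ([KR][ILV]{2}X{3,7}P)
# can only occur where planted
_BACKGROUND_ALPHABET = "ACDEFGHIKLMNQRSTVWY"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator.

    Defaults mirror the scale of the analysis this package supports: a
    90-species eukaryote panel, 70 gene families, moderate per-branch loss
    (0.15) and strong loss coupling (0.9) within complexes.
    """

    n_species: int = 90
    seed: int = 42
    origin_policy: str | frozenset = "root"  # "root" | "uniform_internal" | clade
    loss_prob: float = 0.15
    n_genes: int = 70
    coupling: float = 0.9
    motif_noise: float = 0.0
    sequence_length: int = 120

    def __post_init__(self) -> None:
        if self.n_species < 4:
            raise ValueError("n_species must be >= 4")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for name in ("loss_prob", "coupling", "motif_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.sequence_length < len(PLANTED_MOTIF) + _MOTIF_OFFSET:
            raise ValueError(
                f"sequence_length must be >= {_MOTIF_OFFSET + len(PLANTED_MOTIF)}"
            )


@dataclass
class SimulatedGene:
    """One simulated gene: true history plus the observable profile."""

    name: str
    profile: PhyloProfile
    true_origin: frozenset[str] | None
    true_losses: tuple[frozenset[str], ...]
    role: str = "independent"  # independent | coupled | multifunctional
    partner: str | None = None
    resamples: int = 0


def _random_codes(n: int, rng: np.random.Generator) -> list[str]:
    upper = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    lower = "abcdefghijklmnopqrstuvwxyz"
    codes: list[str] = []
    seen: set[str] = set()
    while len(codes) < n:
        code = upper[rng.integers(26)] + "".join(
            lower[rng.integers(26)] for _ in range(3)
        )
        if code not in seen:
            seen.add(code)
            codes.append(code)
    return codes


def simulate_species_tree(n_species: int, seed: int) -> SpeciesTree:
    """Random rooted binary tree by sequential leaf addition.

    Leaf codes are collision-free random 4-letter strings; the result is a
    deterministic function of (n_species, seed).
    """
    if n_species < 4:
        raise ValueError("n_species must be >= 4")
    rng = np.random.default_rng(seed)
    codes = _random_codes(n_species, rng)
    root: list = [codes[0], codes[1]]
    leaf_refs: list[tuple[list, int]] = [(root, 0), (root, 1)]
    for code in codes[2:]:
        pick = int(rng.integers(len(leaf_refs)))
        container, idx = leaf_refs[pick]
        new = [container[idx], code]
        container[idx] = new
        leaf_refs[pick] = (new, 0)
        leaf_refs.append((new, 1))

    def to_newick(node) -> str:
        if isinstance(node, str):
            return node
        return "(" + ",".join(to_newick(c) for c in node) + ")"

    return SpeciesTree.from_newick(to_newick(root) + ";")


def _pick_origin(tree: SpeciesTree, config: SimulationConfig, rng: np.random.Generator):
    policy = config.origin_policy
    if policy == "root":
        return tree.root
    if policy == "uniform_internal":
        internal = tree.internal_nodes()
        return internal[int(rng.integers(len(internal)))]
    if isinstance(policy, (frozenset, set)):
        return tree.node_for_clade(frozenset(policy))
    raise ValueError(f"unknown origin policy {policy!r}")


def _draw_losses(
    tree: SpeciesTree, origin, loss_prob: float, rng: np.random.Generator
) -> list[frozenset[str]]:
    """Per-branch loss events below ``origin``; a lost lineage stays lost."""
    losses: list[frozenset[str]] = []

    def walk(node) -> None:
        for child in tree.children(node):
            if rng.random() < loss_prob:
                losses.append(tree.clade(child))
            else:
                walk(child)

    walk(origin)
    return losses


def _presence_from_history(
    tree: SpeciesTree, origin, losses: list[frozenset[str]]
) -> frozenset[str]:
    present = set(tree.clade(origin))
    for clade in losses:
        present -= clade
    return frozenset(present)


def _profile_from_codes(
    name: str, tree: SpeciesTree, present: frozenset[str]
) -> PhyloProfile:
    vec = [1 if c in present else 0 for c in tree.leaf_codes]
    return PhyloProfile.from_presence(name, tree.leaf_codes, vec)


def simulate_gene_history(
    tree: SpeciesTree,
    config: SimulationConfig,
    gene_seed: int,
    *,
    name: str | None = None,
    keep_extinct: bool = False,
) -> SimulatedGene:
    """Single-origin gene with independent per-branch stochastic losses.

    A gene lost from every leaf is extinct; observed orthogroups are
    conditioned on survival, so extinct draws are resampled (with the
    resample count recorded) unless ``keep_extinct`` is set.
    """
    name = name or f"gene{gene_seed:04d}"
    for attempt in range(_MAX_RESAMPLES + 1):
        rng = np.random.default_rng([config.seed, gene_seed, attempt])
        origin = _pick_origin(tree, config, rng)
        losses = _draw_losses(tree, origin, config.loss_prob, rng)
        present = _presence_from_history(tree, origin, losses)
        if present or keep_extinct:
            return SimulatedGene(
                name=name,
                profile=_profile_from_codes(name, tree, present),
                true_origin=tree.clade(origin),
                true_losses=tuple(losses),
                role="independent",
                resamples=attempt,
            )
    raise RuntimeError(
        f"gene {name}: extinct in {_MAX_RESAMPLES} consecutive resamples "
        f"(loss_prob={config.loss_prob})"
    )


def _maximal_clades(clades: list[frozenset[str]]) -> tuple[frozenset[str], ...]:
    """Drop clades nested inside another (keep only maximal loss branches)."""
    out = []
    for c in clades:
        if not any(c < other for other in clades):
            out.append(c)
    # de-duplicate, deterministic order
    seen: set[frozenset[str]] = set()
    uniq = []
    for c in sorted(out, key=lambda s: sorted(s)):
        if c not in seen:
            seen.add(c)
            uniq.append(c)
    return tuple(uniq)


def simulate_coupled_pair(
    tree: SpeciesTree,
    config: SimulationConfig,
    pair_seed: int,
    *,
    names: tuple[str, str] | None = None,
) -> tuple[SimulatedGene, SimulatedGene]:
    """Two genes originating at the same node with coupled loss events.

    Losses are drawn for gene A at ``loss_prob``; each A-loss is copied to B
    with probability ``coupling``, and B draws additional independent losses
    at rate ``loss_prob * (1 - coupling)``.  With coupling 1 the profiles are
    identical; with coupling 0 the histories are independent.
    """
    name_a, name_b = names or (f"pair{pair_seed:04d}A", f"pair{pair_seed:04d}B")
    for attempt in range(_MAX_RESAMPLES + 1):
        rng = np.random.default_rng([config.seed, pair_seed, attempt, 1])
        origin = _pick_origin(tree, config, rng)
        losses_a = _draw_losses(tree, origin, config.loss_prob, rng)
        copied = [c for c in losses_a if rng.random() < config.coupling]
        extra = _draw_losses(
            tree, origin, config.loss_prob * (1.0 - config.coupling), rng
        )
        losses_b = _maximal_clades(copied + extra)
        present_a = _presence_from_history(tree, origin, losses_a)
        present_b = _presence_from_history(tree, origin, list(losses_b))
        if present_a and present_b:
            gene_a = SimulatedGene(
                name=name_a,
                profile=_profile_from_codes(name_a, tree, present_a),
                true_origin=tree.clade(origin),
                true_losses=tuple(losses_a),
                role="coupled",
                partner=name_b,
                resamples=attempt,
            )
            gene_b = SimulatedGene(
                name=name_b,
                profile=_profile_from_codes(name_b, tree, present_b),
                true_origin=tree.clade(origin),
                true_losses=losses_b,
                role="coupled",
                partner=name_a,
                resamples=attempt,
            )
            return gene_a, gene_b
    raise RuntimeError(f"pair {name_a}/{name_b}: extinct in all resamples")


def simulate_multifunctional_triplet(
    tree: SpeciesTree,
    config: SimulationConfig,
    seed: int,
    *,
    names: tuple[str, str, str] | None = None,
) -> tuple[SimulatedGene, SimulatedGene, SimulatedGene]:
    """An enzyme retained iff at least one of two partners is present.

    Partners are simulated as a (possibly coupled) pair; the enzyme's
    presence is their elementwise OR, flipped per species with probability
    ``motif_noise``.  The enzyme has no single-gain loss history of its own —
    its profile is defined by the retention rule.
    """
    enzyme_name, name_a, name_b = names or (
        f"enzyme{seed:04d}",
        f"partner{seed:04d}A",
        f"partner{seed:04d}B",
    )
    partner_a, partner_b = simulate_coupled_pair(
        tree, config, seed, names=(name_a, name_b)
    )
    rng = np.random.default_rng([config.seed, seed, 0, 2])
    union = (partner_a.profile.presence | partner_b.profile.presence).astype(np.int8)
    flips = rng.random(len(union)) < config.motif_noise
    presence = np.where(flips, 1 - union, union)
    enzyme = SimulatedGene(
        name=enzyme_name,
        profile=PhyloProfile.from_presence(enzyme_name, tree.leaf_codes, presence),
        true_origin=None,
        true_losses=(),
        role="multifunctional",
        partner=f"{name_a}|{name_b}",
    )
    return enzyme, partner_a, partner_b


def simulate_gene_set(
    tree: SpeciesTree, config: SimulationConfig
) -> list[SimulatedGene]:
    """``config.n_genes`` independent genes with seeds 1..n_genes."""
    return [simulate_gene_history(tree, config, g) for g in range(1, config.n_genes + 1)]


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    idx = rng.integers(len(_BACKGROUND_ALPHABET), size=length)
    return "".join(_BACKGROUND_ALPHABET[i] for i in idx)


def emit_fixture_dataset(
    genes: list[SimulatedGene],
    tree: SpeciesTree,
    config: SimulationConfig,
    outdir: str | Path,
    *,
    motif_pairs: Mapping[str, str] | None = None,
) -> dict[str, Path]:
    """Write a complete on-disk fixture: FASTA per gene, tree, truth, config.

    Sequences are random residue strings (no substitution model — they exist
    to exercise I/O and motif scanning).  For a gene named in ``motif_pairs``
    (carrier -> partner gene name), each sequence carries a planted canonical
    MIM iff the partner is present in that species, flipped per species with
    probability ``motif_noise``.  Output is bit-reproducible given the config
    seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    motif_pairs = dict(motif_pairs or {})
    by_name = {g.name: g for g in genes}
    for carrier, partner in motif_pairs.items():
        if carrier not in by_name or partner not in by_name:
            raise KeyError(f"motif pair {carrier}->{partner}: unknown gene name")
    if len(genes) > 100 or len(tree) > 9999:
        raise ValueError("fixture id scheme supports <= 100 genes, <= 9999 species")

    paths: dict[str, Path] = {}
    codes = tree.leaf_codes
    for gi, gene in enumerate(genes):
        rng = np.random.default_rng([config.seed, 104729, gi])
        partner_pres = None
        if gene.name in motif_pairs:
            partner_pres = dict(
                zip(codes, by_name[motif_pairs[gene.name]].profile.presence)
            )
        lines = []
        for si, code in enumerate(codes):
            n_copies = int(gene.profile.copy_number[si])
            for _ in range(n_copies):
                seq = _random_sequence(config.sequence_length, rng)
                if partner_pres is not None:
                    plant = bool(partner_pres[code])
                    if rng.random() < config.motif_noise:
                        plant = not plant
                    if plant:
                        seq = (
                            seq[:_MOTIF_OFFSET]
                            + PLANTED_MOTIF
                            + seq[_MOTIF_OFFSET + len(PLANTED_MOTIF) :]
                        )
                lines.append(f">{code}{gi:02d}{si:04d}\n{seq}\n")
        fasta = outdir / f"{gene.name}.fasta"
        fasta.write_text("".join(lines))
        paths[gene.name] = fasta

    tree_path = outdir / "tree.nwk"
    tree_path.write_text(tree.as_newick() + "\n")
    paths["tree"] = tree_path

    truth_lines = ["gene\trole\tpartner\torigin\tlosses\tprofile\n"]
    for gene in genes:
        origin = ";".join(sorted(gene.true_origin)) if gene.true_origin else ""
        losses = "|".join(";".join(sorted(c)) for c in gene.true_losses)
        prof = "".join(str(int(p)) for p in gene.profile.presence)
        truth_lines.append(
            f"{gene.name}\t{gene.role}\t{gene.partner or ''}\t{origin}\t{losses}\t{prof}\n"
        )
    truth_path = outdir / "truth.tsv"
    truth_path.write_text("".join(truth_lines))
    paths["truth"] = truth_path

    config_path = outdir / "config.yaml"
    cfg = asdict(config)
    if isinstance(cfg["origin_policy"], frozenset):
        cfg["origin_policy"] = sorted(cfg["origin_policy"])
    config_path.write_text(yaml.safe_dump(cfg, sort_keys=True))
    paths["config"] = config_path
    return paths
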