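"""Co-evolution of binary phylogenetic profiles.

Two proteins whose presences and absences across genomes track one another
have likely co-evolved as a functional unit.  Similarity between binary
profiles is measured with the Pearson correlation coefficient r (on 0/1
vectors this is the phi coefficient of the 2x2 co-occurrence table).  An
interaction threshold on r is calibrated by sweeping for a requested fold
enrichment of established interacting pairs, profiles are clustered with
average linkage on d = 1 - r, and query profiles can be matched against a
reference family profile set to nominate new functional partners.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage

from .profiles import PhyloProfile, check_shared_catalog


def profile_pearson(a: Sequence[int], b: Sequence[int]) -> float:
    """Pearson r between two equal-length vectors (phi on binary input).

    Constant input has no defined correlation; by convention 0.0 is returned
    (callers that need to know use :meth:`PhyloProfile.is_constant` or the
    ``constant_flags`` of :class:`CorrelationMatrix`).
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("profiles must be 1-d with length >= 2")
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
    return max(-1.0, min(1.0, r))


@dataclass
class CorrelationMatrix:
    """All pairwise profile correlations for an ordered protein list.

    Rows/columns of constant (all-0 or all-1) profiles are set to 0 and
    flagged; they carry no co-evolution signal and are excluded from
    threshold calibration.
    """

    proteins: tuple[str, ...]
    r: np.ndarray
    constant_flags: np.ndarray

    def __post_init__(self) -> None:
        self.proteins = tuple(self.proteins)
        self._index = {p: i for i, p in enumerate(self.proteins)}

    def pair(self, a: str, b: str) -> float:
        return float(self.r[self._index[a], self._index[b]])

    def informative_pairs(self) -> list[tuple[str, str, float]]:
        """All unordered pairs of non-constant proteins with their r."""
        out = []
        for i, j in combinations(range(len(self.proteins)), 2):
            if self.constant_flags[i] or self.constant_flags[j]:
                continue
            out.append((self.proteins[i], self.proteins[j], float(self.r[i, j])))
        return out


def correlation_matrix(profiles: list[PhyloProfile]) -> CorrelationMatrix:
    """Score every unordered pair of profiles with :func:`profile_pearson`."""
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    check_shared_catalog(profiles)
    names = tuple(p.protein_name for p in profiles)
    mat = np.vstack([p.presence.astype(float) for p in profiles])
    constant = np.array([p.is_constant() for p in profiles], dtype=bool)
    n = len(profiles)
    r = np.zeros((n, n))
    for i in range(n):
        if constant[i]:
            continue
        r[i, i] = 1.0
        for j in range(i + 1, n):
            if constant[j]:
                continue
            r[i, j] = r[j, i] = profile_pearson(mat[i], mat[j])
    return CorrelationMatrix(names, r, constant)


def joint_profile(
    components: list[PhyloProfile], name: str = "joint"
) -> PhyloProfile:
    """Elementwise union of profiles (copy numbers summed).

    The joint profile of a multifunctional protein's partners is the expected
    profile of the protein itself, if it is retained whenever at least one
    partner is present.
    """
    if not components:
        raise ValueError("joint_profile needs at least one component")
    codes = check_shared_catalog(components)
    total = np.sum([p.copy_number for p in components], axis=0)
    return PhyloProfile(name, codes, total)


@dataclass
class CalibrationResult:
    """Outcome of the interaction-enrichment threshold sweep.

    ``threshold`` is the smallest observed r at which the precision among
    pairs scoring >= threshold reaches ``fold`` times the base rate, or the
    sentinel -1.0 when no candidate achieves it.  ``fold`` is the enrichment
    achieved at the returned threshold.
    """

    threshold: float
    fold: float
    base_rate: float
    sweep: list[tuple[float, float]] = field(default_factory=list)

    SENTINEL = -1.0

    @property
    def attained(self) -> bool:
        return self.threshold != self.SENTINEL


def calibrate_threshold(
    matrix: CorrelationMatrix,
    reference: Iterable[frozenset[str]] | Iterable[tuple[str, str]],
    fold: float = 6.0,
) -> CalibrationResult:
    """Find the smallest r threshold with >= ``fold`` interaction enrichment.

    Enrichment at candidate t = (fraction of pairs with r >= t that are in
    the reference) / (reference fraction among all informative pairs).
    Candidates are the distinct observed r values; pairs involving constant
    profiles are excluded.
    """
    if fold <= 0:
        raise ValueError("fold must be positive")
    ref = {frozenset(p) for p in reference}
    if not ref:
        raise ValueError("interaction reference is empty")
    for pair in ref:
        if len(pair) != 2:
            raise ValueError(f"reference pair {sorted(pair)} is not a 2-set")
        missing = [x for x in pair if x not in matrix.proteins]
        if missing:
            raise ValueError(f"reference labels not in matrix: {missing}")
    pairs = matrix.informative_pairs()
    if not pairs:
        raise ValueError("no informative (non-constant) profile pairs")
    labels = [frozenset((a, b)) for a, b, _ in pairs]
    rvals = np.array([r for _, _, r in pairs])
    in_ref = np.array([lbl in ref for lbl in labels])
    base_rate = in_ref.mean()
    sweep: list[tuple[float, float]] = []
    best: tuple[float, float] | None = None
    for t in sorted(set(rvals)):
        sel = rvals >= t
        precision = in_ref[sel].mean()
        enrichment = precision / base_rate if base_rate > 0 else np.inf
        sweep.append((float(t), float(enrichment)))
        if best is None and enrichment >= fold:
            best = (float(t), float(enrichment))
    if best is None:
        return CalibrationResult(
            CalibrationResult.SENTINEL, 0.0, float(base_rate), sweep
        )
    return CalibrationResult(best[0], best[1], float(base_rate), sweep)


@dataclass
class LinkageResult:
    """Average-linkage merge history on d = 1 - r.

    ``merges`` is a scipy-format linkage matrix over ``labels`` (which are
    sorted lexicographically before clustering so that ties break
    deterministically); ``leaf_order`` is the dendrogram leaf ordering.
    """

    labels: tuple[str, ...]
    merges: np.ndarray
    leaf_order: tuple[str, ...]


def cluster_profiles(matrix: CorrelationMatrix) -> LinkageResult:
    """UPGMA-style average-linkage clustering of profiles on d = 1 - r."""
    if len(matrix.proteins) < 2:
        raise ValueError("need at least 2 proteins to cluster")
    order = np.array(sorted(range(len(matrix.proteins)), key=lambda i: matrix.proteins[i]))
    labels = tuple(matrix.proteins[i] for i in order)
    d = 1.0 - matrix.r[np.ix_(order, order)]
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite distances in correlation matrix")
    np.fill_diagonal(d, 0.0)
    iu = np.triu_indices(len(labels), k=1)
    condensed = d[iu]
    merges = linkage(condensed, method="average")
    leaf_order = tuple(labels[i] for i in leaves_list(merges))
    return LinkageResult(labels, merges, leaf_order)


def family_top_matches(
    query: PhyloProfile,
    families: Mapping[str, PhyloProfile],
    k: int = 30,
) -> list[tuple[str, float]]:
    """Rank reference family profiles by correlation with ``query``.

    Returns the top ``k`` (family id, r) pairs, descending r, ties broken by
    family id.  Mirrors screening a genome-wide family database (e.g.
    PANTHER-style assignments) for profiles resembling a protein of interest.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if not families:
        raise ValueError("family profile set is empty")
    scored = [
        (fam, profile_pearson(query.presence, prof.presence))
        for fam, prof in families.items()
    ]
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored[:k]


def family_profiles_from_assignments(
    assignments: Mapping[str, str], catalog
) -> dict[str, PhyloProfile]:
    """Binary family profiles from sequence-id -> family-id assignments.

    A family is present in a species if at least one of that species'
    sequences is assigned to it.
    """
    from .profiles import parse_species_code

    present: dict[str, set[str]] = {}
    for seq_id, fam in assignments.items():
        code = parse_species_code(seq_id)
        if code in catalog:
            present.setdefault(fam, set()).add(code)
    out = {}
    for fam, codes_present in sorted(present.items()):
        vec = [1 if c in codes_present else 0 for c in catalog.codes]
        out[fam] = PhyloProfile.from_presence(fam, catalog.codes, vec)
    return out


def recurrent_families(
    toplists: Mapping[str, list[tuple[str, float]]], min_count: int
) -> list[tuple[str, int]]:
    """Families appearing in >= ``min_count`` of the per-query top lists."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if not toplists:
        raise ValueError("toplists is empty")
    counts: dict[str, int] = {}
    for ranked in toplists.values():
        for fam in {fam for fam, _ in ranked}:
            counts[fam] = counts.get(fam, 0) + 1
    hits = [(fam, n) for fam, n in counts.items() if n >= min_count]
    hits.sort(key=lambda t: (-t[1], t[0]))
    return hits
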