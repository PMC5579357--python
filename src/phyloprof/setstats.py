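"""Conservation statistics for protein sets (e.g. kinetochore vs APC/C).

Summaries of how widely and how evenly a machine's subunits are retained
across a species panel: occurrence frequency, binary profile entropy,
completeness conditioned on anchor proteins that mark possession of the
machine, nonparametric comparison of loss frequencies between two sets, and
rank correlation of loss frequency with sequence-evolution rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import PhyloProfile, check_shared_catalog


def occurrence_frequency(profile: PhyloProfile) -> float:
    """Fraction of species possessing the protein."""
    return float(profile.presence.mean())


def profile_entropy(profile: PhyloProfile) -> float:
    """Binary entropy (bits) of the presence fraction.

    Maximal (1 bit) for a protein present in exactly half the species; 0 for
    a protein present everywhere or nowhere.
    """
    p = occurrence_frequency(profile)
    if p in (0.0, 1.0):
        return 0.0
    return float(-p * np.log2(p) - (1 - p) * np.log2(1 - p))


@dataclass
class ProteinSetDefinition:
    """A named protein set with anchor proteins marking machine possession.

    Anchors are proteins whose joint presence indicates the species has the
    machine at all (e.g. the DNA- and microtubule-binding ends of the
    kinetochore), so completeness is only meaningful where they are present.
    """

    name: str
    members: tuple[str, ...]
    anchors: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.members = tuple(self.members)
        self.anchors = tuple(self.anchors)
        if not self.members:
            raise ValueError(f"protein set {self.name!r} has no members")


@dataclass
class CompletenessResult:
    """Per-species set completeness, anchored and unanchored.

    ``mean_anchored`` averages over species where all anchors are present;
    ``mean_all`` averages over the whole panel (reported alongside because
    summaries are sometimes quoted either way).
    """

    per_species: dict[str, float]
    mean_anchored: float
    mean_all: float
    anchored_species: tuple[str, ...] = field(default_factory=tuple)


def conditional_completeness(
    profiles: Sequence[PhyloProfile], setdef: ProteinSetDefinition
) -> CompletenessResult:
    """Fraction of set members present per species, anchored on ``setdef.anchors``."""
    codes = check_shared_catalog(profiles)
    by_name = {p.protein_name: p for p in profiles}
    missing = [m for m in setdef.members + setdef.anchors if m not in by_name]
    if missing:
        raise KeyError(f"profiles missing for: {missing}")
    member_mat = np.vstack([by_name[m].presence for m in setdef.members])
    frac_all = member_mat.mean(axis=0)
    if setdef.anchors:
        anchor_mat = np.vstack([by_name[a].presence for a in setdef.anchors])
        passing = np.all(anchor_mat == 1, axis=0)
    else:
        passing = np.ones(len(codes), dtype=bool)
    if not passing.any():
        raise ValueError(
            f"no species carries all anchors {setdef.anchors} of set {setdef.name!r}"
        )
    per_species = {
        code: float(frac_all[i]) for i, code in enumerate(codes) if passing[i]
    }
    return CompletenessResult(
        per_species=per_species,
        mean_anchored=float(frac_all[passing].mean()),
        mean_all=float(frac_all.mean()),
        anchored_species=tuple(c for c, ok in zip(codes, passing) if ok),
    )


def compare_loss_frequencies(
    losses_a: Sequence[float], losses_b: Sequence[float]
) -> tuple[float, float, tuple[float, float]]:
    """Two-sided Mann-Whitney rank test between two loss-count samples.

    Returns (U statistic, p value, (mean_a, mean_b)).  The exact null
    distribution is used for small samples (both n <= 25), the tie-corrected
    normal approximation otherwise.
    """
    a = np.asarray(losses_a, dtype=float)
    b = np.asarray(losses_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need >= 2 observations")
    method = "exact" if max(len(a), len(b)) <= 25 else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue), (float(a.mean()), float(b.mean()))


def correlate_loss_vs_rate(
    losses: Mapping[str, float],
    rates: Mapping[str, Mapping[str, float]],
    rate_field: str = "dnds",
) -> tuple[float, float]:
    """Spearman rank correlation of loss counts against an evolution-rate field.

    ``rate_field`` selects ``"dnds"`` or ``"pct_id"`` from the rate table;
    only proteins present in both mappings are used (>= 3 required).
    """
    if rate_field not in ("dnds", "pct_id"):
        raise ValueError(f"unknown rate field {rate_field!r}")
    shared = sorted(set(losses) & set(rates))
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared proteins, have {len(shared)}")
    x = [losses[p] for p in shared]
    y = [rates[p][rate_field] for p in shared]
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def copy_number_summary(
    profiles: Sequence[PhyloProfile],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Copy-number matrix plus per-protein max/mean and a duplication flag.

    A protein with >= 2 copies in any species is flagged as a duplication
    candidate (recurrently duplicated genes show up this way).
    """
    codes = check_shared_catalog(profiles)
    matrix = pd.DataFrame(
        [p.copy_number for p in profiles],
        index=[p.protein_name for p in profiles],
        columns=list(codes),
    )
    matrix.index.name = "protein"
    summary = pd.DataFrame(
        {
            "max_copies": matrix.max(axis=1),
            "mean_copies": matrix.mean(axis=1),
            "duplicated": matrix.max(axis=1) >= 2,
        }
    )
    return matrix, summary


def set_summary(
    profiles: Sequence[PhyloProfile], names: Iterable[str] | None = None
) -> pd.DataFrame:
    """Per-protein occurrence frequency and entropy table."""
    wanted = set(names) if names is not None else None
    rows = []
    for p in profiles:
        if wanted is not None and p.protein_name not in wanted:
            continue
        rows.append(
            {
                "protein": p.protein_name,
                "occurrence_frequency": occurrence_frequency(p),
                "entropy_bits": profile_entropy(p),
            }
        )
    return pd.DataFrame(rows).set_index("protein")
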