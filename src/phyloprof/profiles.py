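"""Species catalogs, orthologous groups and phylogenetic profiles.

A phylogenetic profile records, for one protein, in which genomes of a fixed,
ordered species panel at least one ortholog was found.  Profiles are the basic
currency of every downstream analysis here (co-evolution scoring, Dollo
parsimony, motif co-occurrence, conservation statistics).

Sequences are identified by a 10-character id: a 4-letter species code (first
letter of the genus + first three letters of the species epithet) followed by
six digits.  The species code is the join key between sequences and the
species catalog.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

SEQ_ID_PATTERN = re.compile(r"^[A-Za-z]{4}[0-9]{6}$")
_CODE_PATTERN = re.compile(r"^[A-Za-z]{4}$")
# 20 standard residues plus X (unknown) and * (stop/truncation marker).
_AA_PATTERN = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYX*]+$", re.IGNORECASE)


def parse_species_code(seq_id: str) -> str:
    """Extract the 4-letter species code from a sequence identifier.

    Raises ``ValueError`` if ``seq_id`` does not match the 4-letters +
    6-digits convention.
    """
    if not isinstance(seq_id, str) or not SEQ_ID_PATTERN.match(seq_id):
        raise ValueError(
            f"sequence id {seq_id!r} does not match the expected "
            "4-letter species code + 6-digit pattern"
        )
    return seq_id[:4]


@dataclass(frozen=True)
class SpeciesCatalog:
    """Fixed, ordered panel of species codes shared by all profiles.

    Parameters
    ----------
    codes
        Ordered, unique 4-letter species codes.  The order is part of the
        catalog's identity: every profile vector is aligned to it.
    names
        Optional mapping code -> full species name.
    supergroups
        Optional mapping code -> eukaryotic supergroup label (Opisthokonta,
        Amoebozoa, Archaeplastida, SAR, Excavata, or free text).
    """

    codes: tuple[str, ...]
    names: Mapping[str, str] | None = None
    supergroups: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "codes", tuple(self.codes))
        if len(self.codes) == 0:
            raise ValueError("species catalog must contain at least one code")
        bad = [c for c in self.codes if not _CODE_PATTERN.match(c)]
        if bad:
            raise ValueError(f"species codes must be 4 letters; offending: {bad}")
        dupes = [c for c, n in Counter(self.codes).items() if n > 1]
        if dupes:
            raise ValueError(f"duplicate species codes in catalog: {dupes}")
        object.__setattr__(
            self, "_index", {c: i for i, c in enumerate(self.codes)}
        )

    def __len__(self) -> int:
        return len(self.codes)

    def __contains__(self, code: str) -> bool:
        return code in self._index

    def index(self, code: str) -> int:
        try:
            return self._index[code]
        except KeyError:
            raise KeyError(f"species code {code!r} not in catalog") from None


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence with a species-coded identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        parse_species_code(self.id)  # validates the id format
        if not self.sequence:
            raise ValueError(f"sequence for {self.id} is empty")
        if not _AA_PATTERN.match(self.sequence):
            raise ValueError(
                f"sequence for {self.id} contains characters outside the "
                "amino-acid alphabet (20 residues plus X/*)"
            )

    @property
    def species_code(self) -> str:
        return self.id[:4]


@dataclass
class OrthoGroup:
    """All orthologs of one protein across the species panel.

    ``members`` may be empty: a protein absent from every genome still has a
    (null) profile.
    """

    protein_name: str
    members: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.protein_name:
            raise ValueError("orthogroup protein_name must be non-empty")


@dataclass(frozen=True)
class PhyloProfile:
    """Presence/absence (and copy-number) vector of a protein over a catalog.

    ``presence`` is derived from ``copy_number`` (present iff >= 1 copy), so
    the two can never disagree.
    """

    protein_name: str
    codes: tuple[str, ...]
    copy_number: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "codes", tuple(self.codes))
        cn = np.asarray(self.copy_number)
        if cn.ndim != 1 or len(cn) != len(self.codes):
            raise ValueError(
                f"profile {self.protein_name!r}: copy_number length "
                f"{cn.shape} does not match catalog size {len(self.codes)}"
            )
        if not np.issubdtype(cn.dtype, np.integer):
            if not np.all(cn == np.floor(cn)):
                raise ValueError(
                    f"profile {self.protein_name!r}: copy numbers must be integers"
                )
            cn = cn.astype(np.int64)
        if np.any(cn < 0):
            raise ValueError(
                f"profile {self.protein_name!r}: copy numbers must be non-negative"
            )
        cn = cn.astype(np.int64)
        cn.setflags(write=False)
        object.__setattr__(self, "copy_number", cn)

    @classmethod
    def from_presence(
        cls, protein_name: str, codes: Sequence[str], presence: Sequence[int]
    ) -> "PhyloProfile":
        """Build a single-copy profile straight from a 0/1 vector."""
        pres = np.asarray(presence)
        if not np.all((pres == 0) | (pres == 1)):
            raise ValueError("presence vector must be binary")
        return cls(protein_name, tuple(codes), pres.astype(np.int64))

    @property
    def presence(self) -> np.ndarray:
        return (self.copy_number >= 1).astype(np.int8)

    @property
    def present_codes(self) -> frozenset[str]:
        return frozenset(c for c, p in zip(self.codes, self.presence) if p)

    def is_constant(self) -> bool:
        """True if the profile is all-present or all-absent (uninformative)."""
        p = self.presence
        return bool(np.all(p == p[0]))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhyloProfile):
            return NotImplemented
        return (
            self.protein_name == other.protein_name
            and self.codes == other.codes
            and np.array_equal(self.copy_number, other.copy_number)
        )

    def __hash__(self) -> int:
        return hash((self.protein_name, self.codes, self.copy_number.tobytes()))


def build_profile(
    group: OrthoGroup, catalog: SpeciesCatalog, *, strict: bool = True
) -> PhyloProfile:
    """Project an orthogroup onto the catalog as a copy-number profile.

    ``copy_number[i]`` counts members whose species code is ``catalog.codes[i]``;
    presence is its support.  A member whose code is not in the catalog raises
    in strict mode (default) and is skipped with a logged warning otherwise.
    """
    counts = np.zeros(len(catalog), dtype=np.int64)
    for rec in group.members:
        code = rec.species_code
        if code not in catalog:
            if strict:
                raise ValueError(
                    f"orthogroup {group.protein_name!r}: member {rec.id} has "
                    f"species code {code!r} absent from the catalog"
                )
            logger.warning(
                "orthogroup %s: skipping member %s (code %s not in catalog)",
                group.protein_name,
                rec.id,
                code,
            )
            continue
        counts[catalog.index(code)] += 1
    return PhyloProfile(group.protein_name, catalog.codes, counts)


def check_shared_catalog(profiles: Iterable[PhyloProfile]) -> tuple[str, ...]:
    """Return the common catalog codes, or raise if profiles disagree."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles given")
    codes = profiles[0].codes
    for p in profiles[1:]:
        if p.codes != codes:
            raise ValueError(
                f"profiles {profiles[0].protein_name!r} and {p.protein_name!r} "
                "are built on different species catalogs"
            )
    return codes
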