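"""Short-linear-motif detection and motif-partner co-occurrence.

Implements the Mad2-interacting motif (MIM) analysis: the canonical MIM is a
positive residue, two aliphatic residues, a 3-7 residue spacer and a proline
([KR][ILV]{2}X{3,7}P); a relaxed definition drops either the positive anchor
or the spacer+proline ([ILV]{2}X{3,7}P or [RK][ILV]{2}).  Motifs are scanned
either over raw sequences or inside a window of alignment columns around a
conserved anchor position, giving a per-species motif profile whose
co-occurrence with a partner protein is tested with an exact one-sided
hypergeometric test.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from math import comb
from typing import Mapping, Sequence

import numpy as np

from .coevolution import profile_pearson
from .profiles import PhyloProfile, SpeciesCatalog, parse_species_code

logger = logging.getLogger(__name__)

# X in a motif definition: any standard residue or the unknown residue X
# (deliberately excludes '*' so a truncation marker never completes a motif).
_ANY = "[ACDEFGHIKLMNPQRSTVWYX]"

_TOKEN = re.compile(
    r"(?P<cls>\[[A-Z]+\])|(?P<any>X)|(?P<lit>[A-WYZ])|(?P<rep>\((\d+)(,(\d+))?\))"
)


def _compile_alternative(definition: str) -> re.Pattern:
    """Translate one motif alternative in class/(n,m) notation into a regex.

    ``[KR][ILV](2)X(3,7)P`` -> ``[KR][ILV]{2}(?:ANY){3,7}?P`` — the bounded
    spacer is lazy so the shortest match per start position is reported.
    Whitespace in the definition is ignored.
    """
    src = definition.replace(" ", "")
    pos = 0
    parts: list[str] = []
    while pos < len(src):
        m = _TOKEN.match(src, pos)
        if not m:
            raise ValueError(f"invalid motif definition {definition!r} at {src[pos:]!r}")
        if m.group("cls"):
            parts.append(m.group("cls"))
        elif m.group("any"):
            parts.append(f"(?:{_ANY})")
        elif m.group("lit"):
            parts.append(m.group("lit"))
        else:  # repetition applies to the previous element
            if not parts:
                raise ValueError(f"repetition without element in {definition!r}")
            lo = m.group(5)
            hi = m.group(7)
            if hi is None:
                parts[-1] = f"(?:{parts[-1]}){{{lo}}}"
            else:
                # lazy: shortest spacer first
                parts[-1] = f"(?:{parts[-1]}){{{lo},{hi}}}?"
        pos = m.end()
    return re.compile("".join(parts))


@dataclass(frozen=True)
class MotifPattern:
    """A named motif with one or more alternative definitions."""

    name: str
    definitions: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "definitions", tuple(self.definitions))
        object.__setattr__(
            self, "_regexes", tuple(_compile_alternative(d) for d in self.definitions)
        )

    @property
    def regexes(self) -> tuple[re.Pattern, ...]:
        return self._regexes


def canonical_mim() -> MotifPattern:
    return MotifPattern("canonical_MIM", ("[KR][ILV](2)X(3,7)P",))


def relaxed_mim() -> MotifPattern:
    return MotifPattern("relaxed_MIM", ("[ILV](2)X(3,7)P", "[RK][ILV](2)"))


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    start: int  # 0-based
    end: int  # half-open
    match: str


def find_motif_occurrences(
    sequence: str, pattern: MotifPattern, sequence_id: str = ""
) -> list[MotifHit]:
    """All distinct motif matches in ``sequence`` (overlaps allowed).

    For each start position the shortest-spacer match is reported (lazy
    bounded gap); matches from different pattern alternatives are merged and
    de-duplicated.
    """
    if not sequence:
        raise ValueError("cannot scan an empty sequence")
    seq = sequence.upper()
    seen: set[tuple[int, int]] = set()
    hits: list[MotifHit] = []
    for regex in pattern.regexes:
        # lookahead wrapper yields overlapping matches, one per start
        for m in re.finditer(f"(?=({regex.pattern}))", seq):
            sub = m.group(1)
            span = (m.start(), m.start() + len(sub))
            if span not in seen:
                seen.add(span)
                hits.append(MotifHit(sequence_id, span[0], span[1], sub))
    hits.sort(key=lambda h: (h.start, h.end))
    return hits


@dataclass(frozen=True)
class MotifProfile:
    """Per-species presence of a motif within one protein's orthologs."""

    protein_name: str
    motif_name: str
    codes: tuple[str, ...]
    presence: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "codes", tuple(self.codes))
        pres = np.asarray(self.presence).astype(np.int8)
        if len(pres) != len(self.codes):
            raise ValueError("motif profile length does not match catalog")
        pres.setflags(write=False)
        object.__setattr__(self, "presence", pres)


def scan_alignment_window(
    alignment: Mapping[str, str],
    pattern: MotifPattern,
    anchor_id: str,
    catalog: SpeciesCatalog,
    *,
    anchor_span: tuple[int, int] | None = None,
    slack: int = 5,
    gap_chars: str = "-.",
) -> MotifProfile:
    """Score motif presence at a conserved alignment position, per species.

    The anchor sequence's motif (its first occurrence, or ``anchor_span`` in
    ungapped residue coordinates) is mapped to alignment columns; every
    sequence is then scanned within that column window extended by ``slack``
    columns on both sides, after stripping gaps.  A species is scored present
    if any of its sequences carries a motif in the window.
    """
    if anchor_id not in alignment:
        raise ValueError(f"anchor {anchor_id!r} not in alignment")
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("ragged alignment")
    aln_len = lengths.pop()

    anchor_aln = alignment[anchor_id]
    anchor_seq = "".join(c for c in anchor_aln if c not in gap_chars)
    if anchor_span is None:
        anchor_hits = find_motif_occurrences(anchor_seq, pattern, anchor_id)
        if not anchor_hits:
            raise ValueError(f"anchor {anchor_id!r} carries no motif")
        anchor_span = (anchor_hits[0].start, anchor_hits[0].end)
    else:
        span_seq = anchor_seq[anchor_span[0] : anchor_span[1]]
        if not find_motif_occurrences(span_seq, pattern, anchor_id):
            raise ValueError(
                f"anchor span {anchor_span} of {anchor_id!r} does not match the motif"
            )

    # residue index -> alignment column for the anchor
    res_to_col = [i for i, c in enumerate(anchor_aln) if c not in gap_chars]
    start_col = res_to_col[anchor_span[0]]
    end_col = res_to_col[anchor_span[1] - 1] + 1
    lo = max(0, start_col - slack)
    hi = min(aln_len, end_col + slack)

    presence = np.zeros(len(catalog), dtype=np.int8)
    for seq_id, aln_seq in alignment.items():
        code = parse_species_code(seq_id)
        if code not in catalog:
            raise ValueError(f"species code {code!r} (from {seq_id}) not in catalog")
        window = "".join(c for c in aln_seq[lo:hi] if c not in gap_chars)
        if not window:
            continue  # all gaps in the window: motif absent here
        if find_motif_occurrences(window, pattern, seq_id):
            presence[catalog.index(code)] = 1
        elif find_motif_occurrences(
            "".join(c for c in aln_seq if c not in gap_chars), pattern, seq_id
        ):
            logger.info(
                "sequence %s carries the motif outside the conserved window; "
                "scored absent",
                seq_id,
            )
    return MotifProfile(anchor_id, pattern.name, catalog.codes, presence)


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N objects, K of them marked, n drawn without replacement; exact integer
    summation over the support.
    """
    for name, v in (("N", N), ("K", K), ("n", n), ("k", k)):
        if not isinstance(v, (int, np.integer)) or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    if K > N or n > N:
        raise ValueError(f"inconsistent counts: K={K}, n={n} exceed N={N}")
    if k > min(K, n):
        raise ValueError(f"k={k} exceeds min(K={K}, n={n})")
    total = comb(N, n)
    tail = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1))
    return tail / total


@dataclass(frozen=True)
class CooccurrenceTable:
    """2x2 co-occurrence of a motif with a partner protein.

    Universe: species carrying the motif's host protein.  ``p_value`` is the
    one-sided (over-representation) hypergeometric tail; ``r`` is the phi/
    Pearson correlation of motif and partner presence on the same universe.
    """

    N: int  # universe size (carrier-present species)
    K: int  # partner present
    n: int  # motif present
    k: int  # both
    p_value: float
    r: float


def motif_partner_cooccurrence(
    motif: MotifProfile,
    partner: PhyloProfile,
    carrier: PhyloProfile,
) -> CooccurrenceTable:
    """Test whether the motif co-occurs with the partner protein.

    Only species possessing the carrier protein (the motif's host) enter the
    universe — a species cannot carry the motif without an ortholog to carry
    it in.
    """
    if not (motif.codes == partner.codes == carrier.codes):
        raise ValueError("motif, partner and carrier must share one catalog")
    carrier_pres = carrier.presence.astype(bool)
    if not carrier_pres.any():
        raise ValueError("carrier protein is absent everywhere: empty universe")
    if np.any(motif.presence.astype(bool) & ~carrier_pres):
        raise ValueError("motif marked present in a species lacking the carrier")
    m = motif.presence[carrier_pres]
    p = partner.presence[carrier_pres]
    N = int(carrier_pres.sum())
    K = int(p.sum())
    n = int(m.sum())
    k = int(np.sum((m == 1) & (p == 1)))
    pval = hypergeom_tail(N, K, n, k)
    r = profile_pearson(m, p) if N >= 2 else 0.0
    return CooccurrenceTable(N, K, n, k, pval, r)
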