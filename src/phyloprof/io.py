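"""File I/O: orthogroup FASTA, profile matrices, alignments and small tables.

All tabular formats are UTF-8 TSV.  Profile matrices are written as
protein x species-code tables of copy numbers (a companion binary view can be
written alongside); round-tripping a matrix reproduces the profiles exactly.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .profiles import OrthoGroup, PhyloProfile, SequenceRecord, check_shared_catalog


def read_orthogroup_fasta(path: str | Path) -> OrthoGroup:
    """Read one orthogroup FASTA file (protein name = file name stem).

    The first whitespace-separated token of each header is the sequence id.
    Empty files and duplicated ids are rejected.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"FASTA file {path} is empty or unreadable")
    ids = [r.id for r in records]
    dupes = sorted(i for i, n in Counter(ids).items() if n > 1)
    if dupes:
        raise ValueError(f"FASTA file {path} contains duplicated ids: {dupes}")
    members = [SequenceRecord(r.id, str(r.seq)) for r in records]
    return OrthoGroup(protein_name=path.stem, members=members)


def read_orthogroup_dir(path: str | Path) -> list[OrthoGroup]:
    """Read every ``*.fasta``/``*.fa``/``*.faa`` file in a directory, sorted by name."""
    path = Path(path)
    files = sorted(
        p for p in path.iterdir() if p.suffix.lower() in {".fasta", ".fa", ".faa"}
    )
    if not files:
        raise ValueError(f"no FASTA files found in {path}")
    return [read_orthogroup_fasta(p) for p in files]


def write_profile_matrix(
    profiles: list[PhyloProfile],
    path: str | Path,
    *,
    binary_path: str | Path | None = None,
) -> None:
    """Write profiles as a protein x species copy-number TSV.

    ``binary_path``, if given, receives the companion 0/1 presence view.
    An empty profile list yields a header-only file.
    """
    if profiles:
        codes = check_shared_catalog(profiles)
        cn = pd.DataFrame(
            [p.copy_number for p in profiles],
            index=[p.protein_name for p in profiles],
            columns=list(codes),
        )
    else:
        cn = pd.DataFrame()
    cn.index.name = "protein"
    cn.to_csv(path, sep="\t")
    if binary_path is not None:
        (cn >= 1).astype(int).to_csv(binary_path, sep="\t")


def read_profile_matrix(path: str | Path) -> list[PhyloProfile]:
    """Read a copy-number TSV back into profiles (round-trip identity)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty and len(df.columns) == 0:
        return []
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
            raise ValueError(f"profile matrix {path} contains non-integer cells")
        values = values.astype(np.int64)
    codes = tuple(str(c) for c in df.columns)
    return [
        PhyloProfile(str(name), codes, row)
        for name, row in zip(df.index, values)
    ]


def read_species_catalog(path: str | Path):
    """Read a species catalog TSV with columns code, [name], [supergroup]."""
    from .profiles import SpeciesCatalog

    df = pd.read_csv(path, sep="\t", dtype=str)
    if "code" not in df.columns:
        raise ValueError(f"catalog file {path} lacks a 'code' column")
    codes = tuple(df["code"])
    names = dict(zip(df["code"], df["name"])) if "name" in df.columns else None
    groups = (
        dict(zip(df["code"], df["supergroup"]))
        if "supergroup" in df.columns
        else None
    )
    return SpeciesCatalog(codes, names=names, supergroups=groups)


def read_interaction_pairs(path: str | Path) -> set[frozenset[str]]:
    """Read an established-interactor list: two tab-separated labels per line."""
    pairs: set[frozenset[str]] = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"malformed interaction line: {line!r}")
        a, b = parts[0], parts[1]
        if a == b:
            raise ValueError(f"self-interaction {a!r} not allowed")
        pairs.add(frozenset((a, b)))
    if not pairs:
        raise ValueError(f"interaction file {path} contains no pairs")
    return pairs


def read_family_assignments(path: str | Path) -> dict[str, str]:
    """Read sequence-id -> family-id assignments (PANTHER-style TSV)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError(f"assignment table {path} needs >= 2 columns")
    return dict(zip(df[cols[0]], df[cols[1]]))


def read_rate_table(path: str | Path) -> dict[str, dict[str, float]]:
    """Read protein -> {dnds, pct_id} rates (e.g. human-mouse Ensembl export)."""
    df = pd.read_csv(path, sep="\t")
    need = {"protein", "dnds", "pct_id"} - set(df.columns)
    if need:
        raise ValueError(f"rate table {path} lacks columns: {sorted(need)}")
    out: dict[str, dict[str, float]] = {}
    for _, row in df.iterrows():
        out[str(row["protein"])] = {
            "dnds": float(row["dnds"]),
            "pct_id": float(row["pct_id"]),
        }
    return out


def read_alignment_fasta(path: str | Path) -> dict[str, str]:
    """Read an aligned FASTA into an ordered id -> aligned-sequence mapping."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"alignment file {path} is empty")
    aln = {r.id: str(r.seq) for r in records}
    lengths = {len(s) for s in aln.values()}
    if len(lengths) > 1:
        raise ValueError(f"alignment {path} is ragged (lengths {sorted(lengths)})")
    return aln
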