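"""Per-column, per-clade conservation of an aligned sequence set.

Works on a fixed multiple sequence alignment whose records are mapped to
clade groups (e.g. mammalian TRPV6, sauropsids, amphibians, fish).  For each
group it computes the modal residue and identity percentage of every column,
finds scaffold windows (runs of well-conserved columns), and flags
fingerprint positions: columns conserved in a focal group but different or
poorly conserved in a contrast group — the signature of clade-specific
functional residues such as the fast-inactivation determinants of mammalian
calcium-selective TRP channels.
"""

from __future__ import annotations

import io
import logging
from collections import Counter
from dataclasses import dataclass
from typing import TextIO

import pandas as pd
from Bio import SeqIO

from .errors import AlignmentError

logger = logging.getLogger(__name__)

GAP = "-"


@dataclass
class GroupedAlignment:
    """Aligned records plus an id -> clade-group mapping."""

    records: list[tuple[str, str]]
    groups: dict[str, str]

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("alignment has no records")
        lengths = {len(s) for _, s in self.records}
        if len(lengths) != 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        ids = [i for i, _ in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentError(f"duplicate sequence ids: {dupes}")
        missing = [i for i in ids if i not in self.groups]
        if missing:
            raise AlignmentError(f"ids without a group: {missing}")

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    def group_sequences(self, group: str) -> list[str]:
        seqs = [s for i, s in self.records if self.groups[i] == group]
        if not seqs:
            raise AlignmentError(f"group {group!r} has no sequences")
        return seqs


@dataclass
class ConservationProfile:
    """Per-column modal residue and identity percent for one group.

    ``columns`` is a DataFrame with index 1..L and columns
    ``modal_residue`` (never the gap character; empty string for all-gap
    columns), ``identity_percent`` and ``n_nongap``.
    """

    group: str
    columns: pd.DataFrame


@dataclass(frozen=True)
class FingerprintHit:
    """A column conserved in the focal group and divergent in the contrast group."""

    column: int
    focal_group: str
    focal_residue: str
    focal_identity: float
    contrast_group: str
    contrast_residue: str
    contrast_identity: float


def read_alignment(fasta: str | TextIO, group_map: str | TextIO) -> GroupedAlignment:
    """Aligned FASTA plus a two-column (id, group) TSV -> GroupedAlignment."""
    handle = io.StringIO(fasta) if isinstance(fasta, str) else fasta
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(handle, "fasta")]
    if not records:
        raise AlignmentError("FASTA stream contains no records")
    text = group_map if isinstance(group_map, str) else group_map.read()
    groups: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise AlignmentError(f"group map line {lineno}: expected 2 tab-separated columns")
        groups[parts[0].strip()] = parts[1].strip()
    return GroupedAlignment(records=records, groups=groups)


def column_identity(ga: GroupedAlignment, group: str) -> ConservationProfile:
    """Modal residue and identity percent of every column for one group.

    Identity = 100 x count(modal residue) / group size, with gapped sequences
    in the denominator.  Modal ties break to the lexicographically smallest
    residue (logged); gaps never win modality.
    """
    seqs = ga.group_sequences(group)
    n = len(seqs)
    rows = []
    for col in range(ga.length):
        counts = Counter(s[col] for s in seqs)
        gap_count = counts.pop(GAP, 0)
        if counts:
            top = max(counts.values())
            tied = sorted(r for r, c in counts.items() if c == top)
            if len(tied) > 1:
                logger.info("group %s column %d: modal tie %s -> %s", group, col + 1, tied, tied[0])
            modal = tied[0]
            identity = 100.0 * counts[modal] / n
        else:  # all-gap column
            modal = ""
            identity = 0.0
        rows.append(
            {
                "modal_residue": modal,
                "identity_percent": identity,
                "n_nongap": n - gap_count,
            }
        )
    df = pd.DataFrame(rows, index=pd.RangeIndex(1, ga.length + 1, name="column"))
    return ConservationProfile(group=group, columns=df)


def scaffold_windows(
    p: ConservationProfile, threshold: float = 70.0, min_len: int = 3
) -> list[tuple[int, int]]:
    """Maximal runs of >= min_len consecutive columns with identity >= threshold.

    Intervals are half-open [start, end) in 1-based column coordinates.
    """
    ok = (p.columns["identity_percent"] >= threshold).to_numpy()
    windows = []
    start = None
    for i, flag in enumerate(ok):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_len:
                windows.append((start + 1, i + 1))
            start = None
    if start is not None and len(ok) - start >= min_len:
        windows.append((start + 1, len(ok) + 1))
    return windows


def fingerprint_positions(
    pa: ConservationProfile,
    pb: ConservationProfile,
    t_high: float = 80.0,
    t_low: float = 50.0,
) -> list[FingerprintHit]:
    """Columns conserved (>= t_high) in the focal profile and divergent in the contrast.

    Divergent means the contrast modal residue differs, or its identity falls
    below t_low.  Both profiles must come from the same alignment length.
    """
    if len(pa.columns) != len(pb.columns):
        raise AlignmentError(
            f"profile lengths differ: {len(pa.columns)} vs {len(pb.columns)}"
        )
    hits = []
    for col in pa.columns.index:
        fa = pa.columns.loc[col]
        fb = pb.columns.loc[col]
        if not fa["modal_residue"] or fa["identity_percent"] < t_high:
            continue
        if (fb["modal_residue"] != fa["modal_residue"]) or (fb["identity_percent"] < t_low):
            hits.append(
                FingerprintHit(
                    column=int(col),
                    focal_group=pa.group,
                    focal_residue=fa["modal_residue"],
                    focal_identity=float(fa["identity_percent"]),
                    contrast_group=pb.group,
                    contrast_residue=fb["modal_residue"],
                    contrast_identity=float(fb["identity_percent"]),
                )
            )
    return hits
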