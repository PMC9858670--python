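"""Alignment and haplotype-table handling.

Sequences are haploid mitochondrial consensus sequences over the alphabet
``{A, C, G, T, N, -}``.  Low-coverage museum specimens carry ``N`` at sites
without reliable base calls; gaps from the multiple alignment are treated as
missing data throughout (intraspecific mtDNA alignments here contain no
modelled indels — the hard-to-align control-region portion is excluded
upstream instead).

Two haplotype-collapsing policies are provided:

``strict``
    Two sequences share a haplotype iff they are identical at every site,
    with ``N`` matching only ``N``.

``merge_compatible``
    Sequences identical at all mutually non-missing sites are merged; the
    representative is the site-wise consensus.  When a sequence is compatible
    with several mutually incompatible haplotypes it is assigned to the
    first-seen compatible haplotype in input order (deterministic).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

ALPHABET = np.frombuffer(b"ACGTN-", dtype="S1")
MISSING = np.frombuffer(b"N-", dtype="S1")

__all__ = [
    "Alignment",
    "GroupAssignment",
    "HaplotypeTable",
    "read_fasta_alignment",
    "write_fasta_alignment",
    "read_groups",
    "write_groups",
    "filter_by_completeness",
    "collapse_haplotypes",
    "effective_length",
]


@dataclass(frozen=True)
class Alignment:
    """An aligned set of equal-length haploid sequences.

    Attributes
    ----------
    ids : tuple of str
        Unique sequence identifiers, in input order.
    data : numpy.ndarray
        ``(n, L)`` array of single-byte characters (dtype ``S1``), uppercase.
    """

    ids: tuple[str, ...]
    data: np.ndarray

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[0] != len(self.ids):
            raise ValueError("data must be (n, L) with one row per id")
        if self.data.shape[1] < 1:
            raise ValueError("alignment length must be positive")
        if len(set(self.ids)) != len(self.ids):
            dup = [i for i, c in Counter(self.ids).items() if c > 1]
            raise ValueError(f"duplicate sequence ids: {dup}")

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def L(self) -> int:
        """Alignment length in sites (bp)."""
        return self.data.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n, L)`` mask, True where the base is ``N`` or ``-``."""
        return (self.data == b"N") | (self.data == b"-")

    @classmethod
    def from_strings(cls, ids, seqs) -> "Alignment":
        ids = tuple(ids)
        seqs = [s.upper() for s in seqs]
        if not seqs:
            raise ValueError("empty alignment")
        L = len(seqs[0])
        for sid, s in zip(ids, seqs):
            if len(s) != L:
                raise ValueError(
                    f"sequence {sid!r} has length {len(s)}, expected {L}"
                )
        data = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), L).copy()
        bad = ~np.isin(data, ALPHABET)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"sequence {ids[i]!r} has non-alphabet character "
                f"{data[i, j].decode()!r} at site {j + 1}"
            )
        return cls(ids, data)

    def sequence(self, sid: str) -> str:
        i = self.ids.index(sid)
        return self.data[i].tobytes().decode()

    def to_strings(self) -> dict[str, str]:
        return {sid: row.tobytes().decode() for sid, row in zip(self.ids, self.data)}

    def subset(self, keep_ids) -> "Alignment":
        keep_ids = list(keep_ids)
        idx = [self.ids.index(i) for i in keep_ids]
        return Alignment(tuple(keep_ids), self.data[idx].copy())

    def missing_fraction(self) -> dict[str, float]:
        """Per-sequence fraction of missing (``N``/``-``) sites."""
        frac = self.missing_mask.mean(axis=1)
        return dict(zip(self.ids, frac.tolist()))


@dataclass(frozen=True)
class GroupAssignment:
    """Mapping of sequence id to group label ("historical"/"modern", ...)."""

    groups: dict[str, str]
    year: dict[str, int] = field(default_factory=dict)
    locality: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("empty group assignment")

    def labels(self) -> tuple[str, ...]:
        """Distinct group labels, in first-seen order."""
        return tuple(dict.fromkeys(self.groups.values()))

    def members(self, label: str) -> list[str]:
        return [i for i, g in self.groups.items() if g == label]

    def sizes(self) -> dict[str, int]:
        return dict(Counter(self.groups.values()))


@dataclass(frozen=True)
class HaplotypeTable:
    """Result of collapsing an alignment into haplotypes.

    Attributes
    ----------
    representatives : dict
        haplotype id -> representative sequence (site-wise consensus under
        ``merge_compatible``, the shared sequence under ``strict``).
    assignment : dict
        individual id -> haplotype id; every individual is mapped.
    policy : str
        Collapsing policy used (recorded for provenance).
    """

    representatives: dict[str, str]
    assignment: dict[str, str]
    policy: str

    @property
    def K(self) -> int:
        """Number of distinct haplotypes."""
        return len(self.representatives)

    @property
    def haplotype_ids(self) -> tuple[str, ...]:
        return tuple(self.representatives)

    def counts(self, groups: GroupAssignment | None = None, label: str | None = None) -> np.ndarray:
        """Haplotype count vector, optionally restricted to one group."""
        if label is not None:
            if groups is None:
                raise ValueError("label requires a GroupAssignment")
            ids = [i for i in self.assignment if groups.groups.get(i) == label]
        else:
            ids = list(self.assignment)
        tally = Counter(self.assignment[i] for i in ids)
        return np.array([tally.get(h, 0) for h in self.representatives], dtype=int)

    def counts_by_group(self, groups: GroupAssignment) -> dict[str, np.ndarray]:
        return {g: self.counts(groups, g) for g in groups.labels()}


def read_fasta_alignment(path, alphabet_policy: str = "strict") -> Alignment:
    """Read a FASTA multiple alignment.

    Parameters
    ----------
    path : path-like
    alphabet_policy : {"strict", "map_to_N"}
        ``strict`` rejects characters outside ``{A,C,G,T,N,-}``;
        ``map_to_N`` maps other IUPAC/unknown letters to ``N``.
    """
    if alphabet_policy not in ("strict", "map_to_N"):
        raise ValueError(f"unknown alphabet_policy {alphabet_policy!r}")
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in ids:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if not ids:
        raise ValueError(f"no FASTA records in {path}")
    L = len(seqs[0])
    for sid, s in zip(ids, seqs):
        if len(s) != L:
            raise ValueError(f"sequence {sid!r} has length {len(s)}, expected {L}")
    if alphabet_policy == "map_to_N":
        allowed = set("ACGTN-")
        seqs = ["".join(c if c in allowed else "N" for c in s) for s in seqs]
    return Alignment.from_strings(ids, seqs)


def write_fasta_alignment(aln: Alignment, path) -> None:
    """Write the alignment as FASTA, wrapped at 60 columns."""
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in aln.to_strings().items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_groups(path) -> GroupAssignment:
    """Read a groups TSV: ``id<TAB>group[<TAB>year][<TAB>locality]`` with header."""
    groups: dict[str, str] = {}
    year: dict[str, int] = {}
    locality: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2 or header[0] != "id" or header[1] != "group":
            raise ValueError("groups TSV must start with 'id<TAB>group' header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"line {lineno}: expected at least 2 columns")
            sid, grp = fields[0], fields[1]
            if sid in groups:
                raise ValueError(f"duplicate id {sid!r} in groups file")
            groups[sid] = grp
            if "year" in header and len(fields) > header.index("year"):
                val = fields[header.index("year")]
                if val:
                    year[sid] = int(val)
            if "locality" in header and len(fields) > header.index("locality"):
                val = fields[header.index("locality")]
                if val:
                    locality[sid] = val
    return GroupAssignment(groups, year, locality)


def write_groups(groups: GroupAssignment, path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tgroup\n")
        for sid, grp in groups.groups.items():
            fh.write(f"{sid}\t{grp}\n")


def filter_by_completeness(aln: Alignment, max_missing_fraction: float) -> Alignment:
    """Drop sequences whose missing-site fraction exceeds the threshold.

    Excluded ids are logged at INFO level.  Raises if nothing survives.
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    frac = aln.missing_mask.mean(axis=1)
    keep = frac <= max_missing_fraction
    excluded = [sid for sid, k in zip(aln.ids, keep) if not k]
    if excluded:
        logger.info(
            "excluding %d sequence(s) above missing fraction %.3g: %s",
            len(excluded), max_missing_fraction, ", ".join(excluded),
        )
    if not keep.any():
        raise ValueError("all sequences excluded by completeness filter")
    return Alignment(
        tuple(sid for sid, k in zip(aln.ids, keep) if k),
        aln.data[keep].copy(),
    )


def _compatible(a: np.ndarray, b: np.ndarray) -> bool:
    both = ~(np.isin(a, MISSING) | np.isin(b, MISSING))
    return bool((a[both] == b[both]).all())


def _consensus(rows: np.ndarray) -> np.ndarray:
    """Site-wise consensus of mutually compatible sequences: first non-missing state."""
    out = np.full(rows.shape[1], b"N", dtype="S1")
    for row in rows:
        fill = (out == b"N") & ~np.isin(row, MISSING)
        out[fill] = row[fill]
    return out


def collapse_haplotypes(
    aln: Alignment,
    missing_policy: str = "strict",
    hap_prefix: str = "H",
) -> HaplotypeTable:
    """Collapse aligned sequences into haplotypes.

    See the module docstring for the two policies.  Haplotype ids are
    ``{hap_prefix}1..{hap_prefix}K`` in first-seen order.
    """
    if missing_policy not in ("strict", "merge_compatible"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    assignment: dict[str, str] = {}
    if missing_policy == "strict":
        seen: dict[bytes, str] = {}
        reps: dict[str, str] = {}
        for sid, row in zip(aln.ids, aln.data):
            key = row.tobytes()
            if key not in seen:
                hid = f"{hap_prefix}{len(seen) + 1}"
                seen[key] = hid
                reps[hid] = key.decode()
            assignment[sid] = seen[key]
        return HaplotypeTable(reps, assignment, "strict")

    members: list[list[int]] = []  # row indices per haplotype, first-seen order
    for i, row in enumerate(aln.data):
        for k, idxs in enumerate(members):
            rep = _consensus(aln.data[idxs])
            if _compatible(row, rep):
                idxs.append(i)
                assignment[aln.ids[i]] = f"{hap_prefix}{k + 1}"
                break
        else:
            members.append([i])
            assignment[aln.ids[i]] = f"{hap_prefix}{len(members)}"
    reps = {
        f"{hap_prefix}{k + 1}": _consensus(aln.data[idxs]).tobytes().decode()
        for k, idxs in enumerate(members)
    }
    return HaplotypeTable(reps, assignment, "merge_compatible")


def effective_length(aln: Alignment, deletion: str = "complete"):
    """Usable site count under a deletion policy.

    ``complete`` returns the number of sites with no missing data in any
    sequence; ``pairwise`` returns an ``(n, n)`` integer matrix of sites
    non-missing in both members of each pair (diagonal: per-sequence
    non-missing count).
    """
    miss = aln.missing_mask
    if deletion == "complete":
        return int((~miss.any(axis=0)).sum())
    if deletion == "pairwise":
        ok = (~miss).astype(np.int64)
        return ok @ ok.T
    raise ValueError(f"unknown deletion policy {deletion!r}")
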