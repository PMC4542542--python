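"""Clone dereplication, authenticity filtering and nucleotide distances.

This module covers the path from raw clone libraries to verified lineage
sets: collapsing clones into sequence types, excluding types likely to be
polymerase artefacts (seen in too few clones or too few independent PCRs),
trimming long fragments to a shorter amplicon window, and uncorrected
(Hamming) pairwise distances between aligned lineages.

All sequences handled here are pre-aligned, equal-length nucleotide
fragments; there is no alignment step.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord
from skbio import DistanceMatrix

from .errors import FormatError, InvalidArgumentError

IUPAC_CHARS = frozenset("ACGTRYSWKMBDHVN-")
UNAMBIGUOUS = frozenset("ACGT")


@dataclass
class SequenceRecord:
    """A single (clone) sequence with its provenance."""

    id: str
    sequence: str
    sample_id: str = ""
    pcr_id: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InvalidArgumentError(f"record {self.id!r}: empty sequence")


@dataclass
class CloneLibrary:
    """All clones obtained from one sample (one cloning reaction or several PCRs)."""

    records: list[SequenceRecord]
    sample_id: str

    def __post_init__(self) -> None:
        for r in self.records:
            if r.sample_id and r.sample_id != self.sample_id:
                raise InvalidArgumentError(
                    f"clone {r.id!r} carries sample_id {r.sample_id!r}, "
                    f"library is {self.sample_id!r}"
                )

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class SequenceType:
    """A distinct sequence with tallies of its support across clones/samples/PCRs."""

    id: str
    sequence: str
    clone_count: int
    n_samples: int
    n_pcrs: int


@dataclass
class LineageSet:
    """An ordered set of aligned, equal-length lineage sequences.

    The unit of every distance and affinity computation.  Identifiers are
    unique; sequences are expected (but not forced) to be pairwise distinct —
    :func:`trim_to_subfragment` can transiently create duplicates that
    :func:`collapse_identical` then removes.
    """

    ids: list[str]
    sequences: list[str]
    fragment_label: str = ""

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise InvalidArgumentError("ids and sequences differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise InvalidArgumentError("duplicate lineage ids")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise InvalidArgumentError(f"sequences not equal length: {sorted(lengths)}")
        self.sequences = [s.upper() for s in self.sequences]

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        """Alignment length in base pairs."""
        return len(self.sequences[0]) if self.sequences else 0

    def sequence_of(self, lineage_id: str) -> str:
        return self.sequences[self.ids.index(lineage_id)]

    def to_records(self) -> list[SequenceRecord]:
        return [SequenceRecord(i, s) for i, s in zip(self.ids, self.sequences)]


# ---------------------------------------------------------------------------
# FASTA I/O


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Sequences are uppercased; duplicate ids, empty files and non-IUPAC
    characters raise :class:`FormatError`.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for idx, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        seq = str(rec.seq).upper()
        bad = set(seq) - IUPAC_CHARS
        if bad:
            raise FormatError(
                f"{path}: record {idx} ({rec.id!r}) contains non-IUPAC "
                f"characters {sorted(bad)}"
            )
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate id {rec.id!r} at record {idx}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    bio = [_BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


def lineage_set_from_fasta(path, fragment_label: str = "") -> LineageSet:
    recs = read_fasta(path)
    return LineageSet([r.id for r in recs], [r.sequence for r in recs], fragment_label)


# ---------------------------------------------------------------------------
# Dereplication and verification


def dereplicate(clones: Sequence[CloneLibrary]) -> list[SequenceType]:
    """Collapse clones into distinct sequence types with support tallies.

    Types are ordered (and numbered) by descending clone count, ties broken
    by sequence lexicographic order, so ids are reproducible.
    """
    all_records = [r for lib in clones for r in lib.records]
    if not all_records:
        return []
    lengths = {len(r.sequence) for r in all_records}
    if len(lengths) > 1:
        raise InvalidArgumentError(
            f"clone sequences must be equal length, got lengths {sorted(lengths)}"
        )
    count: dict[str, int] = defaultdict(int)
    samples: dict[str, set] = defaultdict(set)
    pcrs: dict[str, set] = defaultdict(set)
    for lib in clones:
        for r in lib.records:
            seq = r.sequence.upper()
            count[seq] += 1
            samples[seq].add(lib.sample_id)
            pcrs[seq].add((lib.sample_id, r.pcr_id))
    ordered = sorted(count, key=lambda s: (-count[s], s))
    width = max(2, len(str(len(ordered))))
    return [
        SequenceType(
            id=f"type_{k + 1:0{width}d}",
            sequence=seq,
            clone_count=count[seq],
            n_samples=len(samples[seq]),
            n_pcrs=len(pcrs[seq]),
        )
        for k, seq in enumerate(ordered)
    ]


def verify_sequence_types(
    types: Sequence[SequenceType],
    min_clones: int = 2,
    min_pcrs: int = 2,
    fragment_label: str = "verified",
    id_prefix: str = "lineage",
) -> tuple[LineageSet, pd.DataFrame]:
    """Retain sequence types unlikely to be polymerase errors.

    A type is authentic when it was seen in at least ``min_clones`` clones
    AND in at least ``min_pcrs`` independent PCRs.  Retained types are
    renumbered as lineages (keeping the dereplication order).  Returns the
    lineage set and a report of discarded types with reasons.
    """
    kept: list[SequenceType] = []
    discarded: list[dict] = []
    for t in types:
        reasons = []
        if t.clone_count < min_clones:
            reasons.append(f"clone_count {t.clone_count} < {min_clones}")
        if t.n_pcrs < min_pcrs:
            reasons.append(f"n_pcrs {t.n_pcrs} < {min_pcrs}")
        if reasons:
            discarded.append(
                {
                    "type_id": t.id,
                    "clone_count": t.clone_count,
                    "n_pcrs": t.n_pcrs,
                    "reason": "; ".join(reasons),
                }
            )
        else:
            kept.append(t)
    report = pd.DataFrame(discarded, columns=["type_id", "clone_count", "n_pcrs", "reason"])
    width = max(2, len(str(len(kept))))
    ids = [f"{id_prefix}_{k + 1:0{width}d}" for k in range(len(kept))]
    return LineageSet(ids, [t.sequence for t in kept], fragment_label), report


# ---------------------------------------------------------------------------
# Trimming / collapsing


def trim_to_subfragment(
    lineages: LineageSet, start: int, end: int, fragment_label: str | None = None
) -> LineageSet:
    """Slice every aligned sequence to the 0-based half-open window [start, end)."""
    L = lineages.length
    if not (0 <= start < end <= L):
        raise InvalidArgumentError(
            f"window [{start}, {end}) out of range for alignment length {L}"
        )
    label = fragment_label if fragment_label is not None else (
        f"{lineages.fragment_label}[{start}:{end}]"
    )
    return LineageSet(list(lineages.ids), [s[start:end] for s in lineages.sequences], label)


def collapse_identical(lineages: LineageSet) -> tuple[LineageSet, dict[str, str]]:
    """Collapse identical sequences, keeping first-occurrence order.

    Returns the reduced lineage set and a total mapping old id -> new id.
    The new id is the id of the first lineage carrying each sequence.
    """
    first: dict[str, str] = {}
    mapping: dict[str, str] = {}
    ids: list[str] = []
    seqs: list[str] = []
    for i, s in zip(lineages.ids, lineages.sequences):
        if s not in first:
            first[s] = i
            ids.append(i)
            seqs.append(s)
        mapping[i] = first[s]
    return LineageSet(ids, seqs, lineages.fragment_label), mapping


# ---------------------------------------------------------------------------
# Distances


def _encode(sequences: Sequence[str]) -> np.ndarray:
    return np.frombuffer("".join(sequences).encode("ascii"), dtype="S1").reshape(
        len(sequences), -1
    )


def hamming_matrix(lineages: LineageSet, site_policy: str = "skip_ambiguous") -> DistanceMatrix:
    """Pairwise uncorrected nucleotide differences (integer counts).

    ``site_policy='skip_ambiguous'`` (default) counts a site only when both
    characters are unambiguous A/C/G/T; ``'strict'`` compares every site
    literally.
    """
    if site_policy not in ("strict", "skip_ambiguous"):
        raise InvalidArgumentError(f"unknown site_policy {site_policy!r}")
    arr = _encode(lineages.sequences)
    n = len(lineages)
    diff = arr[:, None, :] != arr[None, :, :]
    if site_policy == "skip_ambiguous":
        ok = np.isin(arr, np.frombuffer(b"ACGT", dtype="S1"))
        comparable = ok[:, None, :] & ok[None, :, :]
        counts = (diff & comparable).sum(axis=2)
    else:
        counts = diff.sum(axis=2)
    np.fill_diagonal(counts, 0)
    return DistanceMatrix(counts.astype(float), ids=list(lineages.ids))


def distance_summary(matrix: DistanceMatrix, L: int) -> dict[str, float]:
    """Mean/max pairwise differences as counts and as percent of fragment length.

    Percentages use the full alignment length ``L`` as denominator and are
    reported to one decimal, matching the convention "x substitutions out of
    L nucleotides".
    """
    n = matrix.shape[0]
    if n < 2:
        raise InvalidArgumentError("distance summary needs at least 2 lineages")
    tri = matrix.data[np.triu_indices(n, k=1)]
    mean_count = float(tri.mean())
    max_count = float(tri.max())
    return {
        "mean_count": round(mean_count, 1),
        "max_count": round(max_count, 1),
        "mean_pct": round(mean_count / L * 100, 1),
        "max_pct": round(max_count / L * 100, 1),
    }


class MatchedPair(NamedTuple):
    id_a: str
    id_b: str
    distance: int
    identical: bool


def match_lineage_sets(
    set_a: LineageSet, set_b: LineageSet, max_mismatch: int = 2
) -> list[MatchedPair]:
    """Cross-set pairs within ``max_mismatch`` nucleotide differences.

    Used to relate lineages recovered from different datasets (e.g. modern
    surface samples vs core horizons) trimmed to the same fragment.  Pairs
    are sorted by distance, then ids; distance-0 pairs are flagged identical.
    """
    if max_mismatch < 0:
        raise InvalidArgumentError("max_mismatch must be >= 0")
    if set_a.length != set_b.length:
        raise InvalidArgumentError(
            f"fragment lengths differ: {set_a.length} vs {set_b.length}"
        )
    a = _encode(set_a.sequences)
    b = _encode(set_b.sequences)
    d = (a[:, None, :] != b[None, :, :]).sum(axis=2)
    pairs = [
        MatchedPair(set_a.ids[i], set_b.ids[j], int(d[i, j]), d[i, j] == 0)
        for i, j in zip(*np.nonzero(d <= max_mismatch))
    ]
    pairs.sort(key=lambda p: (p.distance, p.id_a, p.id_b))
    return pairs
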