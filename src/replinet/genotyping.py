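"""Mutation calling and consensus genotyping for long-read replicator populations.

Reads (full-length amplicon consensus sequences of host and parasitic RNAs)
are globally aligned to the ancestral host reference, per-read mutations are
called, mutations that rise above a frequency threshold in at least one
serial-transfer round form the *dominant mutation panel*, and every read is
projected onto that panel to yield consensus genotypes with per-round counts
and frequencies.

Coordinates are 1-based and inclusive. Deletions are anchored at the first
deleted reference base and left-normalized (shifted to the lowest equivalent
coordinate) so that alternative gap placements of the same event map to one
canonical call. Insertions relative to the reference are recorded but are
never eligible for the dominant panel.
"""

from __future__ import annotations

import functools
from collections import Counter
from collections.abc import Collection, Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align, SeqIO

__all__ = [
    "MutationCall",
    "MutationPanel",
    "Genotype",
    "GenotypeTable",
    "align_to_reference",
    "call_mutations",
    "call_reads",
    "classify_reads",
    "find_dominant_mutations",
    "mutation_frequencies",
    "build_consensus_genotypes",
    "top_genotypes",
    "left_normalize",
]

_KIND_RANK = {"substitution": 0, "deletion": 1, "insertion": 2}


@dataclass(frozen=True)
class MutationCall:
    """One mutation relative to the ancestral reference.

    Parameters
    ----------
    position
        1-based reference coordinate. For deletions this is the first
        deleted base; for insertions, the reference base immediately after
        the inserted run.
    kind
        ``"substitution"``, ``"deletion"`` or ``"insertion"``.
    ref
        Reference base (substitutions only).
    alt
        Alternative base (substitutions) or inserted sequence (insertions).
    length
        Number of deleted reference bases (deletions; 1 otherwise).
    """

    position: int
    kind: str
    ref: str | None = None
    alt: str | None = None
    length: int = 1

    def __post_init__(self) -> None:
        if self.kind not in _KIND_RANK:
            raise ValueError(f"unknown mutation kind: {self.kind!r}")
        if self.position < 1:
            raise ValueError("position must be >= 1 (1-based coordinates)")
        if self.kind == "substitution":
            if self.ref is None or self.alt is None or self.ref == self.alt:
                raise ValueError("substitution requires ref and alt bases, ref != alt")
        if self.kind == "deletion" and self.length < 1:
            raise ValueError("deletion length must be >= 1")

    @property
    def sort_key(self) -> tuple:
        return (self.position, _KIND_RANK[self.kind], self.alt or "", self.length)

    @property
    def label(self) -> str:
        if self.kind == "substitution":
            return f"{self.ref}{self.position}{self.alt}"
        if self.kind == "deletion":
            return f"del{self.position}_{self.length}"
        return f"ins{self.position}_{self.alt}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def left_normalize(call: MutationCall, reference: str) -> MutationCall:
    """Shift a deletion to its lowest equivalent reference coordinate.

    A deletion inside a repeat admits several alignments with identical
    score; the canonical representative anchors it as far left as possible
    (the convention used by VCF normalizers). Substitutions and insertions
    are returned unchanged.
    """
    if call.kind != "deletion":
        return call
    pos = call.position  # 1-based first deleted base
    length = call.length
    while pos > 1 and reference[pos - 2] == reference[pos + length - 2]:
        pos -= 1
    if pos == call.position:
        return call
    return MutationCall(position=pos, kind="deletion", length=length)


@functools.lru_cache(maxsize=8)
def _aligner(match: float, mismatch: float, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def _check_sequence(seq: str, name: str) -> str:
    if not seq:
        raise ValueError(f"{name} sequence is empty")
    seq = seq.upper().replace("U", "T")
    if not set(seq) <= set("ACGTN"):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"{name} contains non-nucleotide characters: {bad}")
    return seq


def align_to_reference(
    read: str,
    reference: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -4.0,
    gap_extend: float = -0.5,
) -> Align.Alignment:
    """Optimal global alignment of ``read`` against ``reference``.

    Affine gap penalties (a gap of length L scores ``gap_open +
    gap_extend * (L - 1)``). Among co-optimal alignments the first in the
    aligner's deterministic enumeration order is returned, so repeated calls
    give identical alignments.
    """
    reference = _check_sequence(reference, "reference")
    read = _check_sequence(read, "read")
    aligner = _aligner(match, mismatch, gap_open, gap_extend)
    return aligner.align(reference, read)[0]


def call_mutations(alignment: Align.Alignment, normalize: bool = True) -> list[MutationCall]:
    """Extract mutation calls from a global alignment (reference = target).

    One substitution per mismatched column, one deletion per maximal run of
    reference bases absent from the read, one insertion per maximal run of
    read bases absent from the reference. Deletions are left-normalized by
    default.
    """
    target = str(alignment.target).upper().replace("U", "T")
    query = str(alignment.query).upper().replace("U", "T")
    t_arr = np.frombuffer(target.encode(), dtype=np.uint8)
    q_arr = np.frombuffer(query.encode(), dtype=np.uint8)
    t_blocks, q_blocks = alignment.aligned

    calls: list[MutationCall] = []
    pt = pq = 0
    n_t = len(target)
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if ts > pt:
            calls.append(MutationCall(position=pt + 1, kind="deletion", length=ts - pt))
        if qs > pq:
            anchor = min(ts + 1, n_t)
            calls.append(MutationCall(position=anchor, kind="insertion", alt=query[pq:qs]))
        diff = np.nonzero(t_arr[ts:te] != q_arr[qs:qe])[0]
        for i in diff:
            calls.append(
                MutationCall(
                    position=ts + int(i) + 1,
                    kind="substitution",
                    ref=target[ts + i],
                    alt=query[qs + i],
                )
            )
        pt, pq = te, qe
    if n_t > pt:
        calls.append(MutationCall(position=pt + 1, kind="deletion", length=n_t - pt))
    if len(query) > pq:
        calls.append(MutationCall(position=n_t, kind="insertion", alt=query[pq:]))
    if normalize:
        calls = [left_normalize(c, target) for c in calls]
    return sorted(calls, key=lambda c: c.sort_key)


def call_reads(
    reads: Iterable,
    reference: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -4.0,
    gap_extend: float = -0.5,
) -> list[frozenset[MutationCall]]:
    """Align and call every read; identical sequences are aligned once."""
    cache: dict[str, frozenset[MutationCall]] = {}
    out: list[frozenset[MutationCall]] = []
    for read in reads:
        seq = str(read.seq) if hasattr(read, "seq") else str(read)
        key = seq.upper().replace("U", "T")
        if key not in cache:
            aln = align_to_reference(key, reference, match, mismatch, gap_open, gap_extend)
            cache[key] = frozenset(call_mutations(aln))
        out.append(cache[key])
    return out


def classify_reads(reads: Iterable, host_length: int, parasite_length: int) -> tuple[list, list]:
    """Split reads into (host, parasite) classes by length.

    Hosts and parasites differ by a large internal deletion, so the length
    midpoint separates the two classes; substitution-level variation does
    not change read length.
    """
    midpoint = (host_length + parasite_length) / 2
    host, parasite = [], []
    for read in reads:
        seq = str(read.seq) if hasattr(read, "seq") else str(read)
        (host if len(seq) >= midpoint else parasite).append(read)
    return host, parasite


PerRoundCalls = Mapping[int, Sequence[Collection[MutationCall]]]


def mutation_frequencies(per_round_calls: PerRoundCalls) -> pd.DataFrame:
    """Per-round read frequency of every called mutation (insertions included).

    Rows are mutation labels (ordered by coordinate), columns are rounds.
    """
    rounds = sorted(per_round_calls)
    all_calls: dict[MutationCall, None] = {}
    freq: dict[int, Counter] = {}
    for rnd in rounds:
        reads = per_round_calls[rnd]
        counts: Counter = Counter()
        for read_calls in reads:
            for call in set(read_calls):
                counts[call] += 1
                all_calls[call] = None
        n = len(reads)
        freq[rnd] = Counter({c: k / n for c, k in counts.items()}) if n else counts
    ordered = sorted(all_calls, key=lambda c: c.sort_key)
    data = {rnd: [freq[rnd].get(c, 0.0) for c in ordered] for rnd in rounds}
    frame = pd.DataFrame(data, index=[c.label for c in ordered])
    frame.insert(0, "position", [c.position for c in ordered])
    frame.insert(1, "kind", [c.kind for c in ordered])
    frame.insert(2, "ref", [c.ref or "" for c in ordered])
    frame.insert(3, "alt", [c.alt or "" for c in ordered])
    frame.insert(4, "length", [c.length for c in ordered])
    return frame


@dataclass(frozen=True)
class MutationPanel:
    """Ordered set of dominant mutations defining the genotype space."""

    mutations: tuple[MutationCall, ...]
    threshold: float = 0.10
    strict: bool = True
    rounds: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.mutations)) != len(self.mutations):
            raise ValueError("panel contains duplicate mutations")

    def __len__(self) -> int:
        return len(self.mutations)

    def __iter__(self):
        return iter(self.mutations)

    def index(self, call: MutationCall) -> int:
        return self.mutations.index(call)

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.mutations]


def find_dominant_mutations(
    per_round_calls: PerRoundCalls,
    threshold: float = 0.10,
    strict: bool = True,
) -> MutationPanel:
    """Mutations whose read frequency exceeds ``threshold`` in >= 1 round.

    ``strict`` selects '> threshold' (default); ``strict=False`` selects
    '>= threshold'. Insertions are excluded from the panel. Panel order is
    (position, kind, alt, length), which is stable across runs.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if not per_round_calls or all(len(v) == 0 for v in per_round_calls.values()):
        raise ValueError("need at least one round with at least one read")
    dominant: dict[MutationCall, None] = {}
    for rnd in sorted(per_round_calls):
        reads = per_round_calls[rnd]
        if not reads:
            continue
        counts: Counter = Counter()
        for read_calls in reads:
            for call in set(read_calls):
                if call.kind != "insertion":
                    counts[call] += 1
        n = len(reads)
        for call, k in counts.items():
            f = k / n
            if (f > threshold) if strict else (f >= threshold):
                dominant[call] = None
    ordered = tuple(sorted(dominant, key=lambda c: c.sort_key))
    return MutationPanel(
        mutations=ordered,
        threshold=threshold,
        strict=strict,
        rounds=tuple(sorted(per_round_calls)),
    )


@dataclass(frozen=True)
class Genotype:
    """A presence/absence combination of panel mutations."""

    presence: tuple[bool, ...]
    counts: Mapping[int, int]
    frequencies: Mapping[int, float]

    @property
    def bitstring(self) -> str:
        return "".join("1" if p else "0" for p in self.presence)

    def mutations(self, panel: MutationPanel) -> list[MutationCall]:
        return [m for m, p in zip(panel.mutations, self.presence) if p]


@dataclass(frozen=True)
class GenotypeTable:
    """Consensus genotypes with per-round counts and frequencies."""

    panel: MutationPanel
    genotypes: tuple[Genotype, ...]
    rounds: tuple[int, ...]
    ids: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.ids:
            object.__setattr__(
                self, "ids", tuple(f"G{i:04d}" for i in range(len(self.genotypes)))
            )

    def __len__(self) -> int:
        return len(self.genotypes)

    def presence_frame(self) -> pd.DataFrame:
        mat = np.array([g.presence for g in self.genotypes], dtype=int)
        mat = mat.reshape(len(self.genotypes), len(self.panel))
        return pd.DataFrame(mat, index=list(self.ids), columns=self.panel.labels)

    def frequency(self, genotype: Genotype, rnd: int) -> float:
        return genotype.frequencies.get(rnd, 0.0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gid, g in zip(self.ids, self.genotypes):
            row: dict = {"genotype": gid, "presence": g.bitstring}
            for rnd in self.rounds:
                row[f"count_r{rnd}"] = g.counts.get(rnd, 0)
                row[f"freq_r{rnd}"] = g.frequencies.get(rnd, 0.0)
            rows.append(row)
        return pd.DataFrame(rows)


def build_consensus_genotypes(per_round_calls: PerRoundCalls, panel: MutationPanel) -> GenotypeTable:
    """Project reads onto the dominant panel and merge identical projections.

    Non-panel mutations (including all insertions) are dropped from each
    read; reads with identical projections collapse into one genotype whose
    per-round frequency is its read count over that round's total read
    count. Projection is idempotent: re-projecting already-projected calls
    changes nothing.
    """
    index = {m: i for i, m in enumerate(panel.mutations)}
    rounds = tuple(sorted(per_round_calls))
    counts: dict[tuple[bool, ...], Counter] = {}
    order: dict[tuple[bool, ...], int] = {}
    for rnd in rounds:
        for read_calls in per_round_calls[rnd]:
            presence = [False] * len(panel)
            for call in read_calls:
                i = index.get(call)
                if i is not None:
                    presence[i] = True
            key = tuple(presence)
            if key not in counts:
                counts[key] = Counter()
                order[key] = len(order)
            counts[key][rnd] += 1
    totals = {rnd: len(per_round_calls[rnd]) for rnd in rounds}
    genotypes = []
    for key in sorted(counts, key=order.get):
        per_round = dict(counts[key])
        freqs = {rnd: per_round.get(rnd, 0) / totals[rnd] for rnd in rounds if totals[rnd]}
        genotypes.append(Genotype(presence=key, counts=per_round, frequencies=freqs))
    return GenotypeTable(panel=panel, genotypes=tuple(genotypes), rounds=rounds)


def top_genotypes(table: GenotypeTable, n: int, rnd: int) -> list[tuple[str, Genotype]]:
    """The ``n`` most frequent genotypes in round ``rnd``.

    Ties are broken by the presence vector: of two equally frequent
    genotypes the one carrying the earlier panel mutation ranks first
    (descending lexicographic order of the bitstring), which is stable
    across runs.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rnd not in table.rounds:
        raise ValueError(f"unknown round {rnd}; table covers {table.rounds}")
    ranked = sorted(
        zip(table.ids, table.genotypes),
        key=lambda item: (-item[1].frequencies.get(rnd, 0.0),) + tuple(not p for p in item[1].presence),
    )
    return ranked[: min(n, len(ranked))]


def read_fasta(path) -> list:
    """Load reads from a FASTA file (thin Bio.SeqIO wrapper)."""
    return list(SeqIO.parse(str(path), "fasta"))
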