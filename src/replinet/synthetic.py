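"""Seeded synthetic stand-ins for replicator sequencing reads and assay tables.

The long-term evolution experiment this package analyzes produced (a)
long-read amplicon populations of a replicase-encoding host RNA (~2,125 nt)
and of internally deleted parasitic RNAs (~500 nt) at many serial-transfer
rounds, and (b) pairwise fold-replication tables from translation-uncoupled
replication assays. This module emulates the *statistical structure* of
those data — lineage-structured mutation sharing, round-by-round frequency
drift, deletion-bearing parasite reads, multiplicative assay noise — so the
whole downstream pipeline is testable without any external download.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .genotyping import MutationCall, left_normalize
from .network import FoldReplicationTable

__all__ = [
    "ReferenceSet",
    "PlantedMutation",
    "EvolutionScenario",
    "ReadSet",
    "generate_references",
    "generate_reads",
    "generate_fold_table",
    "default_scenario",
    "five_species_rates",
    "write_fasta",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ReferenceSet:
    """Ancestral host reference and its internally deleted parasite.

    The parasite retains the host's 5' and 3' terminal regions (needed for
    replicase recognition) and deletes one internal block of the replicase
    gene: ``parasite_seq = host[:prefix] + host[prefix + deletion_length:]``.
    """

    host_id: str
    host_seq: str
    parasite_id: str
    parasite_seq: str
    deletion_start: int  # 1-based first deleted host base
    deletion_length: int

    def __post_init__(self) -> None:
        prefix = self.deletion_start - 1
        expected = (
            self.host_seq[:prefix] + self.host_seq[prefix + self.deletion_length :]
        )
        if expected != self.parasite_seq:
            raise ValueError("parasite_seq is not host prefix + suffix for the stated deletion")
        if not self.host_seq or not self.parasite_seq:
            raise ValueError("sequences must be non-empty")

    @property
    def host_length(self) -> int:
        return len(self.host_seq)

    @property
    def parasite_length(self) -> int:
        return len(self.parasite_seq)

    def host_to_parasite(self, position: int) -> int:
        """Map a 1-based host coordinate into parasite coordinates."""
        prefix = self.deletion_start - 1
        if position <= prefix:
            return position
        if position >= self.deletion_start + self.deletion_length:
            return position - self.deletion_length
        raise ValueError(f"host position {position} lies inside the parasite deletion")

    def structural_deletion(self) -> MutationCall:
        """The parasite's defining deletion, as a canonical mutation call."""
        call = MutationCall(
            position=self.deletion_start, kind="deletion", length=self.deletion_length
        )
        return left_normalize(call, self.host_seq)


def generate_references(
    host_length: int = 2125,
    parasite_length: int = 500,
    deletion_anchor: int | None = None,
    seed: int = 0,
) -> ReferenceSet:
    """Random host reference plus a deletion-derived parasite.

    ``deletion_anchor`` is the 1-based host coordinate of the first deleted
    base; by default the retained sequence is split evenly between the two
    termini. Base composition is uniform (GC 0.5).
    """
    if not 0 < parasite_length < host_length:
        raise ValueError("require 0 < parasite_length < host_length")
    if deletion_anchor is None:
        deletion_anchor = parasite_length // 2 + 1
    prefix = deletion_anchor - 1
    suffix = parasite_length - prefix
    if prefix < 1 or suffix < 1:
        raise ValueError("deletion must preserve both terminal regions")
    rng = np.random.default_rng(seed)
    host = "".join(rng.choice(_BASES, size=host_length))
    deletion_length = host_length - parasite_length
    parasite = host[:prefix] + host[prefix + deletion_length :]
    return ReferenceSet(
        host_id="host_ref",
        host_seq=host,
        parasite_id="parasite_ref",
        parasite_seq=parasite,
        deletion_start=deletion_anchor,
        deletion_length=deletion_length,
    )


@dataclass(frozen=True)
class PlantedMutation:
    """A mutation planted in one lineage (host reference coordinates)."""

    position: int
    alt: str | int  # base => substitution, int => deletion of that length
    lineage: str

    @property
    def kind(self) -> str:
        return "deletion" if isinstance(self.alt, int) else "substitution"


@dataclass(frozen=True)
class EvolutionScenario:
    """Planted lineage structure and per-round frequency trajectories.

    Lineages are mutation-nested: a sublineage inherits every mutation of
    its ancestors (via ``parents``) and adds its own. ``classes`` assigns
    each lineage to the host or parasite read class; parasite-lineage reads
    are built on the parasite reference, so they carry the structural
    deletion in addition to planted mutations. Within a round, any host
    frequency mass not assigned to a lineage goes to unmutated ancestor
    reads.
    """

    rounds: tuple[int, ...]
    planted_mutations: tuple[PlantedMutation, ...]
    trajectories: Mapping[str, Mapping[int, float]]
    parents: Mapping[str, str | None]
    classes: Mapping[str, str]
    reads_per_round: int = 1000
    error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.reads_per_round < 1:
            raise ValueError("reads_per_round must be positive")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must lie in [0, 1)")
        for lineage, traj in self.trajectories.items():
            if lineage not in self.classes:
                raise ValueError(f"lineage {lineage!r} has no class assignment")
            for rnd, f in traj.items():
                if not 0 <= f <= 1:
                    raise ValueError(f"frequency {f} of {lineage!r} at round {rnd} not in [0,1]")
        for rnd in self.rounds:
            total = sum(t.get(rnd, 0.0) for t in self.trajectories.values())
            if total > 1 + 1e-12:
                raise ValueError(f"lineage frequencies at round {rnd} sum to {total} > 1")
        for cls in self.classes.values():
            if cls not in ("host", "parasite"):
                raise ValueError(f"unknown read class {cls!r}")

    @property
    def lineages(self) -> tuple[str, ...]:
        return tuple(self.trajectories)

    def lineage_mutations(self, lineage: str) -> tuple[PlantedMutation, ...]:
        """All mutations carried by a lineage, ancestors included."""
        chain: list[str] = []
        node: str | None = lineage
        while node is not None:
            chain.append(node)
            node = self.parents.get(node)
        wanted = set(chain)
        return tuple(m for m in self.planted_mutations if m.lineage in wanted)

    def to_yaml(self, path) -> None:
        payload = {
            "rounds": list(self.rounds),
            "planted_mutations": [
                {"position": m.position, "alt": m.alt, "lineage": m.lineage}
                for m in self.planted_mutations
            ],
            "trajectories": {
                lin: {int(r): float(f) for r, f in traj.items()}
                for lin, traj in self.trajectories.items()
            },
            "parents": dict(self.parents),
            "classes": dict(self.classes),
            "reads_per_round": self.reads_per_round,
            "error_rate": self.error_rate,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "EvolutionScenario":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            rounds=tuple(payload["rounds"]),
            planted_mutations=tuple(
                PlantedMutation(m["position"], m["alt"], m["lineage"])
                for m in payload["planted_mutations"]
            ),
            trajectories={
                lin: {int(r): float(f) for r, f in traj.items()}
                for lin, traj in payload["trajectories"].items()
            },
            parents=dict(payload["parents"]),
            classes=dict(payload["classes"]),
            reads_per_round=int(payload["reads_per_round"]),
            error_rate=float(payload["error_rate"]),
            seed=int(payload["seed"]),
        )


@dataclass(frozen=True)
class ReadSet:
    """Reads of one round, with the ground-truth lineage of every read.

    FASTA output carries only round and serial number in read IDs; the
    truth labels exist solely for the test harness.
    """

    round: int
    records: tuple[SeqRecord, ...]
    lineages: tuple[str, ...]

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"read": [r.id for r in self.records], "lineage": self.lineages}
        )


def _effective_alt(refs: ReferenceSet, position: int, alt: str) -> str:
    """Requested alt base, cycled to the next base if it equals the reference.

    Scenarios are written without knowledge of the (random) reference, so a
    planted alt may coincide with the reference base; the deterministic
    remap keeps every planted mutation a genuine substitution while read
    generation and the truth panel stay consistent.
    """
    ref_base = refs.host_seq[position - 1]
    if alt != ref_base:
        return alt
    order = "ACGT"
    return order[(order.index(alt) + 1) % 4]


def _apply_mutations(seq: str, mutations: Sequence[PlantedMutation], refs: ReferenceSet, cls: str) -> str:
    """Apply planted mutations (host coordinates) to a class reference."""
    chars = list(seq)
    subs = [m for m in mutations if m.kind == "substitution"]
    dels = [m for m in mutations if m.kind == "deletion"]
    for m in subs:
        idx = (m.position if cls == "host" else refs.host_to_parasite(m.position)) - 1
        chars[idx] = _effective_alt(refs, m.position, str(m.alt))
    for m in sorted(dels, key=lambda m: -m.position):
        idx = (m.position if cls == "host" else refs.host_to_parasite(m.position)) - 1
        del chars[idx : idx + int(m.alt)]
    return "".join(chars)


def generate_reads(scenario: EvolutionScenario, refs: ReferenceSet, rnd: int) -> ReadSet:
    """Sample one round's read population.

    Each read is its lineage's consensus sequence (class reference plus the
    lineage's nested planted mutations) with i.i.d. per-base substitution
    errors at ``scenario.error_rate``. Lineage membership is drawn from the
    round's trajectory frequencies; leftover mass produces unmutated
    ancestor (host) reads.
    """
    if rnd not in scenario.rounds:
        raise ValueError(f"round {rnd} not in scenario rounds {scenario.rounds}")
    rng = np.random.default_rng([scenario.seed, rnd])
    lineages = list(scenario.lineages)
    probs = np.array([scenario.trajectories[l].get(rnd, 0.0) for l in lineages])
    leftover = 1.0 - probs.sum()
    labels = lineages + ["ancestor"]
    probs = np.append(probs, max(leftover, 0.0))
    probs = probs / probs.sum()

    consensus: dict[str, str] = {"ancestor": refs.host_seq}
    for lin in lineages:
        cls = scenario.classes[lin]
        base = refs.host_seq if cls == "host" else refs.parasite_seq
        consensus[lin] = _apply_mutations(base, scenario.lineage_mutations(lin), refs, cls)

    choice = rng.choice(len(labels), size=scenario.reads_per_round, p=probs)
    records: list[SeqRecord] = []
    truth: list[str] = []
    for i, c in enumerate(choice):
        lin = labels[c]
        seq = consensus[lin]
        if scenario.error_rate > 0:
            arr = np.array(list(seq))
            mask = rng.random(arr.size) < scenario.error_rate
            n_err = int(mask.sum())
            if n_err:
                # substitute with one of the three other bases, uniformly
                offsets = rng.integers(1, 4, size=n_err)
                base_idx = np.searchsorted(_BASES, arr[mask])
                arr[mask] = _BASES[(base_idx + offsets) % 4]
            seq = "".join(arr)
        records.append(
            SeqRecord(Seq(seq), id=f"r{rnd}_{i:05d}", description="")
        )
        truth.append(lin)
    return ReadSet(round=rnd, records=tuple(records), lineages=tuple(truth))


def write_fasta(readset: ReadSet, path) -> None:
    """Write one round's reads as FASTA (IDs carry no lineage truth)."""
    SeqIO.write(list(readset.records), str(path), "fasta")


def generate_fold_table(
    true_rates: pd.DataFrame,
    noise_sd: float = 0.0,
    seed: int = 0,
    replicates: int = 3,
) -> FoldReplicationTable:
    """Fold-replication measurements implied by a rate matrix.

    Under first-order replication over unit reaction time the fold equals
    ``exp(k_ij)``; measurements are perturbed by multiplicative log-normal
    noise with log-scale standard deviation ``noise_sd``.
    """
    if (true_rates.to_numpy() < 0).any():
        raise ValueError("rate matrix entries must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for template in true_rates.index:
        for source in true_rates.columns:
            k = float(true_rates.loc[template, source])
            for rep in range(1, replicates + 1):
                noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
                rows.append(
                    {
                        "template": template,
                        "source": source,
                        "replicate": rep,
                        "fold": float(np.exp(k + noise)),
                    }
                )
    return FoldReplicationTable(data=pd.DataFrame(rows), normalized=True)


def five_species_rates() -> pd.DataFrame:
    """Bundled five-species rate matrix (three hosts, two parasites).

    Entry (i, j) is k_ij, the rate at which replicase translated from host
    RNA j replicates template RNA i; parasite columns are zero because
    parasites encode no replicase. The pattern mirrors the endpoint of the
    evolved network: HL2's replicase is a generalist that replicates every
    member, HL1 replicates itself and is helped by HL2, HL3 depends mostly
    on HL2, PL2 is an HL2-specific parasite and PL3 a general parasite.
    """
    species = ["HL1", "HL2", "HL3", "PL2", "PL3"]
    k = pd.DataFrame(0.0, index=species, columns=species)
    k.loc["HL1", "HL1"] = 2.0
    k.loc["HL1", "HL2"] = 0.7
    k.loc["HL2", "HL2"] = 2.0
    k.loc["HL3", "HL1"] = 0.2
    k.loc["HL3", "HL2"] = 0.8
    k.loc["HL3", "HL3"] = 0.3
    k.loc["PL2", "HL2"] = 2.4
    k.loc["PL3", "HL1"] = 2.2
    k.loc["PL3", "HL2"] = 1.0
    k.loc["PL3", "HL3"] = 1.5
    return k


def default_scenario(
    reads_per_round: int = 1000,
    error_rate: float = 0.001,
    seed: int = 0,
) -> EvolutionScenario:
    """Bundled five-lineage desk-scale scenario.

    Three nested host lineages (HL1, HL2 and its sublineage HL3) and two
    nested parasite lineages (PL2 and its sublineage PL3): the structure of
    the evolved population. Early rounds are dominated by the ancestor and
    fluctuate; late rounds settle into stable coexistence. Each lineage
    carries 4-6 private substitutions placed away from the parasite
    deletion boundaries, so lineages are well separated in Hamming space.
    """
    muts = (
        # HL1: 6 private substitutions
        PlantedMutation(40, "A", "HL1"),
        PlantedMutation(333, "C", "HL1"),
        PlantedMutation(707, "G", "HL1"),
        PlantedMutation(1099, "T", "HL1"),
        PlantedMutation(1501, "A", "HL1"),
        PlantedMutation(1905, "C", "HL1"),
        # HL2: 5 private substitutions
        PlantedMutation(111, "G", "HL2"),
        PlantedMutation(555, "T", "HL2"),
        PlantedMutation(931, "A", "HL2"),
        PlantedMutation(1333, "G", "HL2"),
        PlantedMutation(1777, "T", "HL2"),
        # HL3 = HL2 + 4 more
        PlantedMutation(201, "C", "HL3"),
        PlantedMutation(803, "A", "HL3"),
        PlantedMutation(1207, "C", "HL3"),
        PlantedMutation(2001, "G", "HL3"),
        # PL2: 5 substitutions in retained parasite regions (1..250, 1876..2125)
        PlantedMutation(30, "T", "PL2"),
        PlantedMutation(90, "A", "PL2"),
        PlantedMutation(160, "G", "PL2"),
        PlantedMutation(1930, "C", "PL2"),
        PlantedMutation(2050, "A", "PL2"),
        # PL3 = PL2 + 4 more
        PlantedMutation(60, "C", "PL3"),
        PlantedMutation(120, "T", "PL3"),
        PlantedMutation(1990, "G", "PL3"),
        PlantedMutation(2100, "T", "PL3"),
    )
    rounds = (1, 2, 3, 4, 5)
    trajectories = {
        "HL1": {1: 0.10, 2: 0.25, 3: 0.10, 4: 0.20, 5: 0.20},
        "HL2": {1: 0.05, 2: 0.15, 3: 0.30, 4: 0.20, 5: 0.20},
        "HL3": {1: 0.00, 2: 0.05, 3: 0.15, 4: 0.20, 5: 0.20},
        "PL2": {1: 0.05, 2: 0.15, 3: 0.25, 4: 0.20, 5: 0.15},
        "PL3": {1: 0.00, 2: 0.05, 3: 0.10, 4: 0.15, 5: 0.15},
    }
    parents = {"HL1": None, "HL2": None, "HL3": "HL2", "PL2": None, "PL3": "PL2"}
    classes = {"HL1": "host", "HL2": "host", "HL3": "host", "PL2": "parasite", "PL3": "parasite"}
    return EvolutionScenario(
        rounds=rounds,
        planted_mutations=muts,
        trajectories=trajectories,
        parents=parents,
        classes=classes,
        reads_per_round=reads_per_round,
        error_rate=error_rate,
        seed=seed,
    )


def lineage_truth_calls(
    scenario: EvolutionScenario, refs: ReferenceSet, lineage: str
) -> frozenset[MutationCall]:
    """Canonical mutation calls carried by one lineage's consensus.

    Includes inherited (ancestral) planted mutations and, for parasite
    lineages, the structural deletion; coordinates are host-reference,
    matching what the calling pipeline reports.
    """
    calls: set[MutationCall] = set()
    for m in scenario.lineage_mutations(lineage):
        if m.kind == "substitution":
            ref_base = refs.host_seq[m.position - 1]
            alt = _effective_alt(refs, m.position, str(m.alt))
            calls.add(MutationCall(m.position, "substitution", ref=ref_base, alt=alt))
        else:
            calls.add(
                left_normalize(
                    MutationCall(m.position, "deletion", length=int(m.alt)), refs.host_seq
                )
            )
    if scenario.classes[lineage] == "parasite":
        calls.add(refs.structural_deletion())
    return frozenset(calls)


def truth_panel(scenario: EvolutionScenario, refs: ReferenceSet) -> dict[str, list[MutationCall]]:
    """Planted dominant-mutation panel per read class, in canonical form.

    Parasite-class mutations are expressed in host-reference coordinates and
    include the structural deletion shared by every parasite read. Useful
    for checking end-to-end recovery by the calling pipeline.
    """
    panels: dict[str, dict[MutationCall, None]] = {"host": {}, "parasite": {}}
    for m in scenario.planted_mutations:
        cls = scenario.classes[m.lineage]
        if m.kind == "substitution":
            ref_base = refs.host_seq[m.position - 1]
            alt = _effective_alt(refs, m.position, str(m.alt))
            call = MutationCall(m.position, "substitution", ref=ref_base, alt=alt)
        else:
            call = left_normalize(
                MutationCall(m.position, "deletion", length=int(m.alt)), refs.host_seq
            )
        panels[cls][call] = None
    panels["parasite"][refs.structural_deletion()] = None
    return {
        cls: sorted(calls, key=lambda c: c.sort_key) for cls, calls in panels.items()
    }
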