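"""Aligned-sequence containers, haplotype collapsing and site classification.

The whole toolkit operates on a single aligned multi-FASTA of equal-length
mtDNA sequences together with a population map (sequence id -> locality).
Columns containing gaps or missing data are removed globally ("complete
deletion") before any statistic is computed, so every downstream module sees
a rectangular {A,C,G,T} matrix.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_CHARS = set("ACGTN-")
MISSING_CHARS = set("N-")
#: unordered base pairs that are transitions (purine<->purine, pyrimidine<->pyrimidine)
TRANSITION_PAIRS = {frozenset("AG"), frozenset("CT")}


class AlignmentError(ValueError):
    """Raised for malformed or inconsistent alignment input."""


class PopulationMapError(ValueError):
    """Raised when the population map and alignment ids disagree."""


@dataclass(frozen=True)
class Alignment:
    """An aligned set of equal-length nucleotide sequences.

    Parameters
    ----------
    ids
        Unique sequence identifiers, in input order.
    seqs
        Upper-case sequences over ``{A, C, G, T, N, -}``, all the same length.
    """

    ids: tuple[str, ...]
    seqs: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and seqs must have equal length")
        if len(self.ids) == 0:
            raise AlignmentError("empty alignment")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise AlignmentError(f"duplicate sequence ids: {dupes}")
        length = len(self.seqs[0])
        if length == 0:
            raise AlignmentError("zero-length sequences")
        for sid, seq in zip(self.ids, self.seqs):
            if len(seq) != length:
                raise AlignmentError(
                    f"sequence {sid!r} has length {len(seq)}, expected {length}"
                )
            bad = set(seq) - VALID_CHARS
            if bad:
                raise AlignmentError(
                    f"sequence {sid!r} contains invalid characters {sorted(bad)}"
                )

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    def to_array(self) -> np.ndarray:
        """Return the alignment as an (n, L) array of single characters."""
        return np.array([list(s) for s in self.seqs], dtype="U1")

    @classmethod
    def from_array(cls, ids: Sequence[str], arr: np.ndarray) -> "Alignment":
        return cls(tuple(ids), tuple("".join(row) for row in arr))

    def subset(self, ids: Sequence[str]) -> "Alignment":
        """Alignment restricted to the given ids (in the given order)."""
        index = {sid: k for k, sid in enumerate(self.ids)}
        missing = [sid for sid in ids if sid not in index]
        if missing:
            raise AlignmentError(f"ids not in alignment: {missing}")
        return Alignment(tuple(ids), tuple(self.seqs[index[sid]] for sid in ids))


@dataclass(frozen=True)
class PopulationMap:
    """Assignment of each sequence id to a population label."""

    assignment: Mapping[str, str]

    @property
    def populations(self) -> tuple[str, ...]:
        """Ordered unique population labels (first-appearance order)."""
        seen: dict[str, None] = {}
        for pop in self.assignment.values():
            seen.setdefault(pop, None)
        return tuple(seen)

    def members(self, pop: str) -> tuple[str, ...]:
        return tuple(sid for sid, p in self.assignment.items() if p == pop)

    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for pop in self.assignment.values():
            out[pop] = out.get(pop, 0) + 1
        return out

    def validate_against(self, aln: Alignment) -> None:
        aln_ids = set(aln.ids)
        map_ids = set(self.assignment)
        only_map = sorted(map_ids - aln_ids)
        only_aln = sorted(aln_ids - map_ids)
        if only_map:
            raise PopulationMapError(
                f"population map ids absent from alignment: {only_map}"
            )
        if only_aln:
            raise PopulationMapError(
                f"alignment ids absent from population map: {only_aln}"
            )


@dataclass(frozen=True)
class HaplotypeTable:
    """Distinct sequences with per-population carrier counts.

    ``counts`` has one row per haplotype (first-occurrence order) and one
    column per population in ``populations`` order; column sums equal the
    population sample sizes.
    """

    haplotypes: tuple[str, ...]
    populations: tuple[str, ...]
    counts: np.ndarray
    #: representative id of the first carrier of each haplotype
    labels: tuple[str, ...] = field(default=())

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def total_counts(self) -> np.ndarray:
        """Carrier count per haplotype pooled over populations."""
        return self.counts.sum(axis=1).astype(int)

    def to_alignment(self) -> Alignment:
        labels = self.labels or tuple(f"H{k + 1}" for k in range(self.n_haplotypes))
        return Alignment(labels, self.haplotypes)


@dataclass(frozen=True)
class SiteSummary:
    """Counts of polymorphic/singleton/informative sites and substitution types."""

    polymorphic_sites: int
    singleton_sites: int
    informative_sites: int
    transitions: int
    transversions: int
    tv_ts_ratio: float
    base_freqs: dict[str, float]


def _parse_popmap(text: str) -> dict[str, str]:
    assignment: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise PopulationMapError(
                f"population map line {lineno}: expected 'id<TAB>population', got {raw!r}"
            )
        sid, pop = (p.strip() for p in parts)
        if sid in assignment:
            raise PopulationMapError(f"duplicate id {sid!r} in population map")
        assignment[sid] = pop
    if not assignment:
        raise PopulationMapError("empty population map")
    return assignment


def read_alignment(fasta_path, popmap_path) -> tuple[Alignment, PopulationMap]:
    """Read and validate an aligned FASTA plus its id->population map.

    Sequences are upper-cased and RNA ``U`` is mapped to ``T``. Every id must
    appear in both files; any length mismatch or unknown character raises
    :class:`AlignmentError` naming the offending sequence.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {fasta_path}")
    ids = tuple(r.id for r in records)
    seqs = tuple(str(r.seq).upper().replace("U", "T") for r in records)
    aln = Alignment(ids, seqs)
    with open(popmap_path) as fh:
        pm = PopulationMap(_parse_popmap(fh.read()))
    pm.validate_against(aln)
    return aln, pm


def filter_sites(aln: Alignment, policy: str = "complete_deletion") -> Alignment:
    """Remove alignment columns containing gaps or missing data.

    Under ``complete_deletion`` every column with ``-`` or ``N`` in *any*
    sequence is dropped; ``none`` returns the alignment unchanged. The kept
    0-based column indices are available via :func:`site_index_map`.
    """
    if policy == "none":
        return aln
    if policy != "complete_deletion":
        raise ValueError(f"unknown site-filter policy {policy!r}")
    arr = aln.to_array()
    keep = ~np.isin(arr, ["-", "N"]).any(axis=0)
    if not keep.any():
        raise AlignmentError("all columns contain gaps or missing data")
    return Alignment.from_array(aln.ids, arr[:, keep])


def site_index_map(aln: Alignment) -> list[int]:
    """0-based original column index for each column kept by complete deletion."""
    arr = aln.to_array()
    keep = ~np.isin(arr, ["-", "N"]).any(axis=0)
    return [int(i) for i in np.flatnonzero(keep)]


def collapse_haplotypes(aln: Alignment, pm: PopulationMap) -> HaplotypeTable:
    """Merge identical sequences into haplotypes with per-population counts.

    Haplotype identity is exact string equality; ordering follows first
    occurrence in the alignment, so the result is invariant to relabeling but
    deterministic for a given input order.
    """
    pm.validate_against(aln)
    pops = pm.populations
    pop_index = {p: j for j, p in enumerate(pops)}
    hap_index: dict[str, int] = {}
    labels: list[str] = []
    rows: list[list[int]] = []
    for sid, seq in zip(aln.ids, aln.seqs):
        j = pop_index[pm.assignment[sid]]
        k = hap_index.get(seq)
        if k is None:
            k = len(hap_index)
            hap_index[seq] = k
            labels.append(sid)
            rows.append([0] * len(pops))
        rows[k][j] += 1
    counts = np.array(rows, dtype=int)
    return HaplotypeTable(tuple(hap_index), pops, counts, tuple(labels))


def classify_sites(aln: Alignment) -> SiteSummary:
    """Classify variable sites and count substitution types.

    A variable site is parsimony-informative iff at least two distinct bases
    are each carried by >= 2 sequences; otherwise it is a singleton site.
    Transitions/transversions are counted over unordered pairs of *distinct
    bases* observed at each variable site (A<->G and C<->T are transitions).
    """
    if aln.n < 2:
        raise AlignmentError("site classification requires at least 2 sequences")
    arr = aln.to_array()
    n_poly = n_singleton = n_informative = 0
    transitions = transversions = 0
    for col in arr.T:
        bases, counts = np.unique(col, return_counts=True)
        if len(bases) < 2:
            continue
        n_poly += 1
        if (counts >= 2).sum() >= 2:
            n_informative += 1
        else:
            n_singleton += 1
        for a in range(len(bases)):
            for b in range(a + 1, len(bases)):
                pair = frozenset((str(bases[a]), str(bases[b])))
                if pair in TRANSITION_PAIRS:
                    transitions += 1
                else:
                    transversions += 1
    flat, flat_counts = np.unique(arr, return_counts=True)
    total = flat_counts.sum()
    base_freqs = {b: 0.0 for b in "ACGT"}
    for b, c in zip(flat, flat_counts):
        if str(b) in base_freqs:
            base_freqs[str(b)] = c / total
    ratio = transversions / transitions if transitions > 0 else float("nan")
    return SiteSummary(
        polymorphic_sites=n_poly,
        singleton_sites=n_singleton,
        informative_sites=n_informative,
        transitions=transitions,
        transversions=transversions,
        tv_ts_ratio=ratio,
        base_freqs=base_freqs,
    )


def write_fasta(aln: Alignment, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in zip(aln.ids, aln.seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


def write_popmap(pm: PopulationMap, path) -> None:
    with open(path, "w") as fh:
        for sid, pop in pm.assignment.items():
            fh.write(f"{sid}\t{pop}\n")


def write_site_classification(aln: Alignment, path) -> None:
    """TSV of 1-based site, class (invariant/singleton/informative), observed bases."""
    arr = aln.to_array()
    with open(path, "w") as fh:
        fh.write("site\tclass\tbases\n")
        for i, col in enumerate(arr.T, start=1):
            bases, counts = np.unique(col, return_counts=True)
            if len(bases) < 2:
                cls = "invariant"
            elif (counts >= 2).sum() >= 2:
                cls = "informative"
            else:
                cls = "singleton"
            fh.write(f"{i}\t{cls}\t{','.join(map(str, bases))}\n")
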