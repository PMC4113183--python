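"""Hierarchical seed-alignment annotation of collapsed reads.

Each unique sequence is tested against an ordered list of reference
libraries (known rat miRNAs first, then miRNAs of all species, then other
sncRNA classes). Alignment is ungapped, sense-strand and substitution-only,
restricted to the first 20 nt of the read (the "seed"), so 3' non-templated
additions never cost mismatches. A sequence is assigned at the first
library producing a hit within that library's mismatch budget and is then
removed from the input of all later libraries, so no read is counted twice.
Sequences hitting nothing stay in the reads-level matrix unnamed.

Also implements the genomic read-cluster thresholds used to screen novel
miRNA candidates (hairpin folding and ML classification are out of scope).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import io as _io

SEED_LENGTH = 20
DEFAULT_MAX_OFFSET = 2


def _as_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class ReferenceLibrary:
    """One ranked reference library.

    ``mismatch_budget`` follows the mapping hierarchy convention: 1 for the
    rank-1 known-miRNA library, 2 for cross-species homolog search,
    configurable (>= 0) for the remaining annotation libraries.
    ``max_offset`` bounds how far the read 5' end may start from the
    consensus 5' end (isomiR 5' fluctuation); ``None`` allows any offset.
    """

    rank: int
    name: str
    entries: tuple[tuple[str, str], ...]
    mismatch_budget: int = 0
    max_offset: int | None = DEFAULT_MAX_OFFSET

    def __post_init__(self) -> None:
        if self.mismatch_budget < 0:
            raise ValueError("mismatch_budget must be >= 0")
        idents = [i for i, _ in self.entries]
        if len(set(idents)) != len(idents):
            dupes = sorted({i for i in idents if idents.count(i) > 1})
            raise ValueError(f"duplicate identifiers in library {self.name!r}: {dupes}")
        for ident, seq in self.entries:
            if not seq:
                raise ValueError(f"empty consensus for {ident!r} in {self.name!r}")

    @classmethod
    def from_fasta(
        cls,
        path: str | Path,
        rank: int,
        name: str | None = None,
        mismatch_budget: int = 0,
        max_offset: int | None = DEFAULT_MAX_OFFSET,
    ) -> "ReferenceLibrary":
        entries = tuple(_io.read_fasta(path))
        return cls(
            rank=rank,
            name=name or Path(path).stem,
            entries=entries,
            mismatch_budget=mismatch_budget,
            max_offset=max_offset,
        )


def seed_align(
    read: str,
    consensus: str,
    budget: int,
    max_offset: int | None = DEFAULT_MAX_OFFSET,
    seed_length: int = SEED_LENGTH,
) -> int | None:
    """Align the read seed to a consensus; return mismatches or None.

    The seed is the first ``min(seed_length, len(read))`` nt of the read.
    It is placed ungapped at each candidate offset of the consensus
    (offsets in ``[-max_offset, max_offset]``, or every overlapping offset
    when ``max_offset`` is None); seed positions falling outside the
    consensus count as mismatches; read bases beyond the seed are ignored
    entirely. The minimum mismatch count over offsets is returned if it is
    within ``budget``, else None.
    """
    if not consensus:
        raise ValueError("empty consensus")
    if not read:
        raise ValueError("empty read")
    if budget < 0:
        raise ValueError("budget must be >= 0")
    r = _as_rna(read)
    c = _as_rna(consensus)
    seed = r[: min(seed_length, len(r))]
    k, L = len(seed), len(c)
    if max_offset is None:
        offsets: Iterable[int] = range(-k + 1, L)
    else:
        offsets = range(-max_offset, max_offset + 1)
    best: int | None = None
    for o in offsets:
        mm = 0
        for i, base in enumerate(seed):
            j = o + i
            if j < 0 or j >= L or c[j] != base:
                mm += 1
        if best is None or mm < best:
            best = mm
    if best is not None and best <= budget:
        return best
    return None


@dataclass
class AnnotationResult:
    """Outcome of hierarchical annotation.

    ``annotations`` has one row per input sequence (library rank/name,
    identifier, seed mismatches; all-NA for unassigned). ``identifier_matrix``
    sums isomiR counts under each canonical identifier. ``reads_matrix`` is
    the untouched input (every sequence, assigned or not). ``library_of``
    maps each identifier to its library name for within-library RPM.
    """

    annotations: pd.DataFrame
    identifier_matrix: pd.DataFrame
    reads_matrix: pd.DataFrame
    library_of: pd.Series


def annotate_matrix(
    matrix: pd.DataFrame,
    libraries: Sequence[ReferenceLibrary],
) -> AnnotationResult:
    """Assign each row sequence of ``matrix`` through the library hierarchy."""
    ranks = [lib.rank for lib in libraries]
    if len(set(ranks)) != len(ranks):
        raise ValueError("library ranks must be unique")
    ordered = sorted(libraries, key=lambda lib: lib.rank)

    rows = []
    for seq in matrix.index:
        hit = None
        for lib in ordered:
            best: tuple[int, str] | None = None
            for ident, cons in lib.entries:
                mm = seed_align(seq, cons, lib.mismatch_budget, lib.max_offset)
                if mm is not None and (best is None or (mm, ident) < best):
                    best = (mm, ident)
            if best is not None:
                hit = (lib.rank, lib.name, best[1], best[0])
                break
        if hit is None:
            rows.append((seq, pd.NA, None, None, pd.NA))
        else:
            rows.append((seq, hit[0], hit[1], hit[2], hit[3]))
    annotations = pd.DataFrame(
        rows, columns=["sequence", "library_rank", "library", "identifier", "mismatches"]
    ).set_index("sequence")

    assigned = annotations.dropna(subset=["identifier"])
    if len(assigned):
        identifier_matrix = (
            matrix.loc[assigned.index]
            .groupby(assigned["identifier"])
            .sum()
            .sort_index()
        )
        identifier_matrix.index.name = "identifier"
        library_of = (
            assigned.drop_duplicates("identifier").set_index("identifier")["library"].sort_index()
        )
    else:
        identifier_matrix = matrix.iloc[:0].copy()
        library_of = pd.Series(dtype=object, name="library")
    return AnnotationResult(
        annotations=annotations,
        identifier_matrix=identifier_matrix,
        reads_matrix=matrix,
        library_of=library_of,
    )


@dataclass(frozen=True)
class ClusterRead:
    start: int
    sequence: str
    count: int


@dataclass(frozen=True)
class ArmPair:
    """Mature arm intervals on a putative hairpin (half-open coordinates).

    Overhangs are evaluated under the idealized duplex pairing
    ``i <-> hairpin_length - 1 - i``: a perfect Drosha/Dicer product leaves
    each arm's 3' end two nucleotides past the paired position of the other
    arm's 5' start.
    """

    five_start: int
    five_end: int
    three_start: int
    three_end: int
    hairpin_length: int

    @property
    def overhang_3p(self) -> int:
        return self.five_start - (self.hairpin_length - self.three_end)

    @property
    def overhang_5p(self) -> int:
        return self.three_start - (self.hairpin_length - self.five_end)


@dataclass
class ReadCluster:
    """Reads sharing a genomic start window around a candidate mature miRNA."""

    members: tuple[ClusterRead, ...]
    arms: ArmPair | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a read cluster needs at least one member")

    @property
    def most_frequent(self) -> ClusterRead:
        return min(self.members, key=lambda r: (-r.count, r.start, r.sequence))

    @property
    def anchor(self) -> int:
        return self.most_frequent.start

    @property
    def five_prime_fluctuation(self) -> int:
        a = self.anchor
        return max(abs(r.start - a) for r in self.members)


def cluster_reads(
    positioned_reads: Iterable[tuple[int, str, int]],
    window: int = 2,
) -> list[ReadCluster]:
    """Greedy clustering of (start, sequence, count) tuples.

    The most frequent unassigned read anchors each cluster and absorbs all
    reads starting within ``window`` nt of it.
    """
    remaining = sorted(
        (ClusterRead(*t) for t in positioned_reads),
        key=lambda r: (-r.count, r.start, r.sequence),
    )
    clusters = []
    while remaining:
        anchor = remaining[0]
        members = tuple(r for r in remaining if abs(r.start - anchor.start) <= window)
        clusters.append(ReadCluster(members=members))
        taken = set(members)
        remaining = [r for r in remaining if r not in taken]
    return clusters


@dataclass(frozen=True)
class CandidateDecision:
    passed: bool
    reasons: tuple[str, ...]


def novel_candidate_filter(
    cluster: ReadCluster,
    rat_specific: bool = False,
    min_count: int = 10,
    min_length: int = 20,
    max_length: int = 23,
    max_fluctuation: int = 2,
    required_overhang: int = 2,
) -> CandidateDecision:
    """Threshold screen for novel miRNA candidate clusters.

    Checks: (i) most frequent read count >= 10, (ii) its length in
    20-23 nt, (iii) 5' start fluctuation within 2 nt; with
    ``rat_specific`` additionally that both arms exist and show perfect
    2-nt 3' overhangs. Every violated rule is reported.
    """
    reasons: list[str] = []
    top = cluster.most_frequent
    if top.count < min_count:
        reasons.append("read_count")
    if not min_length <= len(top.sequence) <= max_length:
        reasons.append("length")
    if cluster.five_prime_fluctuation > max_fluctuation:
        reasons.append("five_prime_fluctuation")
    if rat_specific:
        if cluster.arms is None:
            reasons.append("arms_missing")
        elif (
            cluster.arms.overhang_3p != required_overhang
            or cluster.arms.overhang_5p != required_overhang
        ):
            reasons.append("overhang")
    return CandidateDecision(passed=not reasons, reasons=tuple(reasons))
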