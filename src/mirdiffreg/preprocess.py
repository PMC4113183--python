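"""Read editing: adapter trimming, length filtering, collapsing.

Raw reads become a "reads-level" matrix of unique 16-41 nt RNA sequences
with per-pool counts. Adapter detection requires at least 10 visible
adapter nucleotides matching with at most one substitution; reads without a
detectable adapter are discarded. Quality scores are ignored throughout.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import io as _io

MIN_LENGTH = 16
MAX_LENGTH = 41
MIN_ADAPTER_OVERLAP = 10
MAX_ADAPTER_MISMATCHES = 1


def _as_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def trim_adapter(
    read: str,
    adapter: str,
    min_overlap: int = MIN_ADAPTER_OVERLAP,
    max_mismatches: int = MAX_ADAPTER_MISMATCHES,
) -> str | None:
    """Strip the 3' adapter, or return None if no adapter is detected.

    The adapter prefix is slid along the read; a hit at position ``p``
    requires at least ``min_overlap`` adapter nucleotides to be visible
    before the read's 3' end and the first ``min_overlap`` of them to match
    the read with at most ``max_mismatches`` substitutions (read bases
    beyond that detection window never block a hit). The leftmost hit wins
    and the read prefix before it is returned (possibly empty).
    """
    if not read:
        raise ValueError("empty read")
    if len(adapter) < min_overlap:
        raise ValueError(
            f"adapter must be at least {min_overlap} nt, got {len(adapter)}"
        )
    r = _as_rna(read)
    a = _as_rna(adapter)
    n = len(r)
    window = a[:min_overlap]
    for p in range(n - min_overlap + 1):
        mismatches = 0
        for i in range(min_overlap):
            if r[p + i] != window[i]:
                mismatches += 1
                if mismatches > max_mismatches:
                    break
        if mismatches <= max_mismatches:
            return r[:p]
    return None


def length_filter(seq: str, min_len: int = MIN_LENGTH, max_len: int = MAX_LENGTH) -> bool:
    """Keep trimmed inserts of 16-41 nt (inclusive)."""
    return min_len <= len(seq) <= max_len


@dataclass
class EditStats:
    """Per-pool bookkeeping of the editing stage."""

    n_input: int = 0
    n_no_adapter: int = 0
    n_length_filtered: int = 0
    n_kept: int = 0


def edit_reads(
    reads: Iterable[str],
    adapter: str,
    min_len: int = MIN_LENGTH,
    max_len: int = MAX_LENGTH,
    stats: EditStats | None = None,
) -> list[str]:
    """Trim and length-filter one pool's raw reads."""
    kept = []
    stats = stats if stats is not None else EditStats()
    for read in reads:
        stats.n_input += 1
        trimmed = trim_adapter(read, adapter)
        if trimmed is None:
            stats.n_no_adapter += 1
            continue
        if not length_filter(trimmed, min_len, max_len):
            stats.n_length_filtered += 1
            continue
        stats.n_kept += 1
        kept.append(trimmed)
    return kept


def collapse(
    reads_by_pool: Mapping[str, Iterable[str]],
    pools: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Collapse edited reads into a unique-sequence x pool count matrix.

    Sequences are normalized to the RNA alphabet (T -> U). Rows are sorted
    lexicographically for determinism.
    """
    pools = list(pools) if pools is not None else list(reads_by_pool)
    counters = {pool: Counter(_as_rna(s) for s in reads_by_pool.get(pool, ())) for pool in pools}
    all_seqs = sorted(set().union(*[c.keys() for c in counters.values()]) if counters else set())
    matrix = pd.DataFrame(
        {pool: [counters[pool].get(s, 0) for s in all_seqs] for pool in pools},
        index=pd.Index(all_seqs, name="sequence"),
        dtype="int64",
    )
    return matrix


def preprocess_fastq(
    fastq_by_pool: Mapping[str, str | Path],
    adapter: str,
    min_len: int = MIN_LENGTH,
    max_len: int = MAX_LENGTH,
) -> tuple[pd.DataFrame, dict[str, EditStats]]:
    """Full editing stage: FASTQ files in, collapsed count matrix out."""
    edited: dict[str, list[str]] = {}
    stats: dict[str, EditStats] = {}
    for pool, path in fastq_by_pool.items():
        st = EditStats()
        edited[pool] = edit_reads(
            _io.iter_fastq_sequences(path), adapter, min_len, max_len, stats=st
        )
        stats[pool] = st
    return collapse(edited, pools=list(fastq_by_pool)), stats
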