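"""GATC fragment indexing and strict read-to-fragment assignment.

DamID resolution is the *GATC fragment*: the genomic interval between two
consecutive DpnI cut sites (DpnI cuts the blunt centre of its GATC
recognition site, GA^TC).  Every downstream profile, HMM state call and
transition map in this package is indexed by these fragments.

Coordinates are 0-based half-open throughout; per chromosome the fragments
are disjoint, adjacent, and tile ``[0, chrom_length)``.  The two
chromosome-end flanks are bounded by only one cut site and are flagged with
``end_flank`` so callers can exclude them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import AlignmentError, MalformedRecordError

#: offset of the DpnI blunt cut within the GATC motif (GA^TC)
CUT_OFFSET = 2

FRAGMENT_COLUMNS = ["chrom", "start", "end", "id", "end_flank"]


def find_gatc_fragments(genome: Mapping[str, str]) -> pd.DataFrame:
    """Build the GATC fragment index for a genome.

    Parameters
    ----------
    genome
        Mapping of chromosome name to sequence.  Sequences are
        uppercase-normalized; ``N`` never matches the motif.

    Returns
    -------
    pandas.DataFrame
        Columns ``chrom, start, end, id, end_flank``, sorted by
        ``(chrom, start)`` with ids assigned in that order.  Fragments on a
        chromosome are adjacent and cover ``[0, len)``.
    """
    rows: list[tuple[str, int, int]] = []
    for chrom in sorted(genome):
        seq = str(genome[chrom]).upper()
        if len(seq) == 0:
            import logging

            logging.getLogger(__name__).warning(
                "chromosome %s has empty sequence; no fragments emitted", chrom
            )
            continue
        cuts = [m + CUT_OFFSET for m in _scan_motif(seq, "GATC")]
        bounds = [0, *cuts, len(seq)]
        for s, e in zip(bounds[:-1], bounds[1:]):
            rows.append((chrom, s, e))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["id"] = np.arange(len(df), dtype=np.int64)
    # flanks touch a chromosome end: first/last fragment of each chromosome
    if len(df):
        first = df.groupby("chrom")["id"].transform("min")
        last = df.groupby("chrom")["id"].transform("max")
        df["end_flank"] = (df["id"] == first) | (df["id"] == last)
    else:
        df["end_flank"] = pd.Series([], dtype=bool)
    return df


def _scan_motif(seq: str, motif: str) -> list[int]:
    """All start offsets of `motif` in `seq` (left to right, non-regex)."""
    out: list[int] = []
    i = seq.find(motif)
    while i != -1:
        out.append(i)
        i = seq.find(motif, i + 1)
    return out


@dataclass
class FragmentCounts:
    """Read counts per GATC fragment for one sample/replicate.

    ``counts[i]`` is the count of fragment id ``i``; the array is aligned to
    the fragment index, so every fragment appears exactly once.
    """

    sample: str
    replicate: str
    counts: np.ndarray
    discarded: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def assign_reads_strict(
    reads: Iterable[tuple[str, int, int]],
    fragments: pd.DataFrame,
    sample: str = "sample",
    replicate: str = "1",
) -> FragmentCounts:
    """Count reads per fragment under strict containment.

    A read increments a fragment's count iff its interval is fully contained
    in that fragment (the ``intersection_strict`` overlap resolution rule);
    reads spanning a DpnI cut site, on unknown chromosomes, or extending
    past a chromosome end are discarded and tallied.

    Parameters
    ----------
    reads
        Iterable of ``(chrom, start, end)`` 0-based half-open intervals.
    fragments
        Fragment index from :func:`find_gatc_fragments`.

    Raises
    ------
    MalformedRecordError
        If a read has ``start >= end``.
    """
    starts: dict[str, np.ndarray] = {}
    ends: dict[str, np.ndarray] = {}
    ids: dict[str, np.ndarray] = {}
    for chrom, sub in fragments.groupby("chrom", sort=False):
        starts[chrom] = sub["start"].to_numpy()
        ends[chrom] = sub["end"].to_numpy()
        ids[chrom] = sub["id"].to_numpy()

    counts = np.zeros(len(fragments), dtype=np.int64)
    discarded = 0
    for lineno, (chrom, rstart, rend) in enumerate(reads, start=1):
        if rstart >= rend:
            raise MalformedRecordError(
                f"read record {lineno}: start {rstart} >= end {rend}"
            )
        if chrom not in starts:
            discarded += 1
            continue
        s = starts[chrom]
        # fragment whose start is the rightmost <= rstart
        j = int(np.searchsorted(s, rstart, side="right")) - 1
        if j < 0 or rend > ends[chrom][j]:
            discarded += 1
            continue
        counts[ids[chrom][j]] += 1
    return FragmentCounts(sample, replicate, counts, discarded)


def check_aligned(fragments: pd.DataFrame, n: int, what: str = "values") -> None:
    """Raise AlignmentError unless `n` matches the fragment universe size."""
    if n != len(fragments):
        raise AlignmentError(
            f"{what} has length {n} but fragment index has {len(fragments)}"
        )
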