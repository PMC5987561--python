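"""TSS regulatory windows, taGATCf mapping, and Pc-target gene groups.

The presumptive regulatory region of a gene spans 2.5 kb upstream to
1.5 kb downstream of its TSS, reflected on the minus strand and clipped to
chromosome bounds.  GATC fragments overlapping a region by at least one
base are its transcription-associated GATC fragments (taGATCf).  A region
is classified from its taGATCf transition labels (gain / loss / mixed /
no_change) and joined with the differential-expression direction of the
gene into groups:

    I  = up   + gain        III = up   + loss       m2 = up   + mixed
    II = down + gain        IV  = down + loss       m1 = down + mixed

Genes whose region shows no change fall in no group ("none").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MalformedRecordError
from .transitions import TransitionCall

DEFAULT_UPSTREAM = 2500
DEFAULT_DOWNSTREAM = 1500

GROUP_TABLE = {
    ("up", "gain"): "I",
    ("down", "gain"): "II",
    ("up", "loss"): "III",
    ("down", "loss"): "IV",
    ("down", "mixed"): "m1",
    ("up", "mixed"): "m2",
    ("up", "no_change"): "none",
    ("down", "no_change"): "none",
}


def build_tss_windows(
    genes: pd.DataFrame,
    chrom_sizes: dict[str, int],
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
) -> pd.DataFrame:
    """Strand-aware TSS windows, clipped to chromosome bounds.

    ``genes`` needs columns ``gene, chrom, tss, strand``.  Plus strand gives
    ``[tss - upstream, tss + downstream)``; minus strand the reflection
    ``[tss - downstream, tss + upstream)``.
    """
    rows = []
    for rec in genes.itertuples(index=False):
        if rec.strand == "+":
            start, end = rec.tss - upstream, rec.tss + downstream
        elif rec.strand == "-":
            start, end = rec.tss - downstream, rec.tss + upstream
        else:
            raise MalformedRecordError(
                f"gene {rec.gene}: unknown strand {rec.strand!r}"
            )
        size = chrom_sizes.get(rec.chrom)
        if size is None:
            raise MalformedRecordError(f"gene {rec.gene}: unknown chromosome {rec.chrom}")
        rows.append(
            {
                "gene": rec.gene,
                "chrom": rec.chrom,
                "start": max(0, start),
                "end": min(size, end),
                "strand": rec.strand,
                "tss": rec.tss,
            }
        )
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "strand", "tss"])


def map_taGATCf(regions: pd.DataFrame, fragments: pd.DataFrame) -> dict[str, np.ndarray]:
    """Associate each gene with fragments overlapping its window by >= 1 bp.

    Fragments tile each chromosome, so the overlap set is the contiguous
    index range with ``frag.start < window.end`` and ``frag.end >
    window.start``.  A fragment may serve multiple genes; genes with no
    overlap get an empty array.
    """
    per_chrom = {
        chrom: (sub["start"].to_numpy(), sub["end"].to_numpy(), sub["id"].to_numpy())
        for chrom, sub in fragments.groupby("chrom", sort=False)
    }
    out: dict[str, np.ndarray] = {}
    for rec in regions.itertuples(index=False):
        prev = out.get(rec.gene)
        if rec.chrom not in per_chrom or rec.end <= rec.start:
            ids = np.array([], dtype=np.int64)
        else:
            starts, ends, fids = per_chrom[rec.chrom]
            lo = int(np.searchsorted(ends, rec.start, side="right"))
            hi = int(np.searchsorted(starts, rec.end, side="left"))
            ids = fids[lo:hi]
        # multiple TSSs per gene: union of their taGATCf
        out[rec.gene] = ids if prev is None else np.union1d(prev, ids)
    return out


def classify_region(labels: np.ndarray | list) -> str:
    """Region class from its taGATCf transition labels.

    gain iff >= 1 gain and no loss; loss iff >= 1 loss and no gain; mixed
    iff both present; no_change otherwise.  Empty input gets ``no_data``
    and is excluded downstream.
    """
    labels = list(labels)
    if not labels:
        return "no_data"
    has_gain = any(l == "gain" or l == 1 for l in labels)
    has_loss = any(l == "loss" or l == -1 for l in labels)
    if has_gain and has_loss:
        return "mixed"
    if has_gain:
        return "gain"
    if has_loss:
        return "loss"
    return "no_change"


def assign_group(region_class: str, direction: str) -> str:
    """Map (DE direction, region class) to group I–IV / m1 / m2 / none."""
    if region_class == "no_data":
        return "none"
    key = (direction, region_class)
    if key not in GROUP_TABLE:
        raise ValueError(f"unknown (direction, class) pair {key!r}")
    return GROUP_TABLE[key]


def integrate(
    de_table: pd.DataFrame,
    genes: pd.DataFrame,
    fragments: pd.DataFrame,
    transitions: TransitionCall,
    chrom_sizes: dict[str, int],
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
    padj_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-gene region assignment joined with DE direction.

    ``de_table`` needs columns ``gene, log2fc, padj``; only genes with
    ``padj < padj_threshold`` are retained, split into up/down by the sign
    of ``log2fc``.  Returns one row per retained gene with columns
    ``gene, direction, region_class, group, n_taGATCf, taGATCf_ids``;
    taGATCf without a defined transition label (masked fragments) do not
    contribute labels.
    """
    de = de_table[de_table["padj"] < padj_threshold].copy()
    de["direction"] = np.where(de["log2fc"] > 0, "up", "down")
    gene_info = genes.set_index("gene")
    regions = build_tss_windows(
        genes[genes["gene"].isin(de["gene"])], chrom_sizes, upstream, downstream
    )
    assoc = map_taGATCf(regions, fragments)
    names = transitions.names()
    rows = []
    for rec in de.itertuples(index=False):
        if rec.gene not in gene_info.index:
            continue
        fids = assoc.get(rec.gene, np.array([], dtype=np.int64))
        labels = [names[f] for f in fids if transitions.defined[f]]
        cls = classify_region(labels)
        rows.append(
            {
                "gene": rec.gene,
                "direction": rec.direction,
                "log2fc": rec.log2fc,
                "padj": rec.padj,
                "region_class": cls,
                "group": assign_group(cls, rec.direction),
                "n_taGATCf": len(fids),
                "taGATCf_ids": ",".join(str(f) for f in fids),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "direction",
            "log2fc",
            "padj",
            "region_class",
            "group",
            "n_taGATCf",
            "taGATCf_ids",
        ],
    )
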