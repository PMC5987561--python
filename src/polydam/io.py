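"""Readers and writers for every external format the pipeline touches.

All coordinates are 0-based half-open internally; conversion happens only
here (WIG is 1-based inclusive, BED 0-based half-open).

The binding-state interchange format is the WIG dialect the published state
calls use: one value per GATC fragment, encoded enriched = 1,
intermediate = 0, depleted = -1, emitted as ``variableStep`` records whose
``span`` is the fragment length (a new declaration line whenever the span
changes).  ``fixedStep`` blocks are accepted on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import MalformedRecordError
from .fragments import FRAGMENT_COLUMNS, FragmentCounts
from .hmm import STATE_DECODING, STATE_ENCODING, StateCall
from .normalize import NormalizedProfile


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# fragments / counts / profiles (TSV + BED)


def write_fragments_bed(fragments: pd.DataFrame, path: str | Path) -> None:
    """Fragment index as BED4: chrom, start, end, id."""
    fragments[["chrom", "start", "end", "id"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_fragments_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "id"]
    )
    first = df.groupby("chrom")["id"].transform("min")
    last = df.groupby("chrom")["id"].transform("max")
    df["end_flank"] = (df["id"] == first) | (df["id"] == last)
    return df[FRAGMENT_COLUMNS]


def write_counts_tsv(
    counts: FragmentCounts, fragments: pd.DataFrame, path: str | Path
) -> None:
    pd.DataFrame(
        {
            "chrom": fragments["chrom"],
            "start": fragments["start"],
            "end": fragments["end"],
            "count": counts.counts,
        }
    ).to_csv(path, sep="\t", index=False)


def read_counts_tsv(
    path: str | Path, sample: str = "sample", replicate: str = "1"
) -> tuple[pd.DataFrame, FragmentCounts]:
    df = pd.read_csv(path, sep="\t")
    frags = df[["chrom", "start", "end"]].copy()
    frags["id"] = np.arange(len(frags), dtype=np.int64)
    return frags, FragmentCounts(sample, replicate, df["count"].to_numpy())


def write_profile_tsv(
    profile: NormalizedProfile, fragments: pd.DataFrame, path: str | Path
) -> None:
    pd.DataFrame(
        {
            "chrom": fragments["chrom"],
            "start": fragments["start"],
            "end": fragments["end"],
            "value": np.where(profile.mask, "NA", np.char.mod("%.6f", profile.values)),
            "masked": profile.mask.astype(int),
        }
    ).to_csv(path, sep="\t", index=False)


def read_profile_tsv(path: str | Path) -> tuple[pd.DataFrame, NormalizedProfile]:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    frags = df[["chrom", "start", "end"]].copy()
    frags["id"] = np.arange(len(frags), dtype=np.int64)
    mask = df["masked"].to_numpy().astype(bool)
    vals = df["value"].to_numpy(dtype=float)
    vals = np.where(mask, np.nan, vals)
    return frags, NormalizedProfile(vals, mask)


def read_bed_intervals(path: str | Path) -> list[tuple[str, int, int]]:
    """BED intervals (first three columns) as (chrom, start, end) tuples."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise MalformedRecordError(f"{path}:{lineno}: fewer than 3 BED fields")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


def read_gene_table(path: str | Path) -> pd.DataFrame:
    """Gene annotation with TSS and strand.

    Accepts the package's TSV (columns gene, chrom, tss, strand, and
    optionally log2fc/padj) or headerless BED6 where the interval start is
    the TSS on + strands and the interval end on - strands.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if "gene" in header and "tss" in header:
        return pd.read_csv(path, sep="\t")
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "gene", "score", "strand"],
    )
    bed["tss"] = np.where(bed["strand"] == "+", bed["start"], bed["end"] - 1)
    return bed[["gene", "chrom", "tss", "strand"]]


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Differential-expression table: gene, log2fc, padj (extra cols kept)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene", "log2fc", "padj"} - set(df.columns)
    if missing:
        raise MalformedRecordError(f"{path}: DE table missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# state WIG (published dialect)


def write_state_wig(
    call: StateCall,
    fragments: pd.DataFrame,
    path: str | Path,
    name: str = "binding_states",
) -> None:
    """Write binding states in the published WIG encoding (1 / 0 / -1).

    One value per unmasked fragment; 1-based start positions, ``span`` equal
    to the fragment length; fragments are emitted in (chrom, start) order;
    masked fragments are omitted.
    """
    if len(call.states) != len(fragments):
        raise MalformedRecordError("state call and fragment index differ in length")
    order = fragments.sort_values(["chrom", "start"]).index.to_numpy()
    with open(path, "w") as fh:
        fh.write(f'track type=wiggle_0 name="{name}"\n')
        cur: tuple[str, int] | None = None
        for i in order:
            if call.missing[i]:
                continue
            chrom = fragments.at[i, "chrom"]
            start = int(fragments.at[i, "start"])
            span = int(fragments.at[i, "end"]) - start
            if cur != (chrom, span):
                fh.write(f"variableStep chrom={chrom} span={span}\n")
                cur = (chrom, span)
            fh.write(f"{start + 1}\t{STATE_ENCODING[int(call.states[i])]}\n")


def read_state_wig(path: str | Path) -> tuple[pd.DataFrame, StateCall]:
    """Read the published state-WIG dialect.

    Returns the fragment intervals (0-based half-open, ids in file order
    after sorting by chrom/start) and the state call.  Values outside
    {-1, 0, 1} and overlapping spans are format errors.
    """
    rows: list[tuple[str, int, int, int]] = []
    chrom: str | None = None
    span = 1
    mode = None  # "variable" | "fixed"
    fixed_pos = 0
    step = 1
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            if line.startswith("variableStep") or line.startswith("fixedStep"):
                fields = dict(
                    kv.split("=", 1) for kv in line.split()[1:] if "=" in kv
                )
                chrom = fields.get("chrom")
                if chrom is None:
                    raise MalformedRecordError(f"{path}:{lineno}: missing chrom=")
                span = int(fields.get("span", 1))
                if line.startswith("fixedStep"):
                    mode = "fixed"
                    fixed_pos = int(fields["start"])
                    step = int(fields.get("step", span))
                else:
                    mode = "variable"
                continue
            if chrom is None or mode is None:
                raise MalformedRecordError(
                    f"{path}:{lineno}: data before any step declaration"
                )
            parts = line.split()
            if mode == "variable":
                if len(parts) != 2:
                    raise MalformedRecordError(
                        f"{path}:{lineno}: variableStep lines need 'pos value'"
                    )
                pos, value = int(parts[0]), parts[1]
            else:
                if len(parts) != 1:
                    raise MalformedRecordError(
                        f"{path}:{lineno}: fixedStep lines carry a single value"
                    )
                pos, value = fixed_pos, parts[0]
                fixed_pos += step
            try:
                enc = int(float(value))
                if float(value) != enc:
                    raise ValueError
            except ValueError:
                raise MalformedRecordError(
                    f"{path}:{lineno}: non-integer state value {value!r}"
                ) from None
            if enc not in STATE_DECODING:
                raise MalformedRecordError(
                    f"{path}:{lineno}: state value {enc} outside {{-1, 0, 1}}"
                )
            rows.append((chrom, pos - 1, pos - 1 + span, STATE_DECODING[enc]))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])
    df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    prev_end = df.groupby("chrom")["end"].shift()
    if ((df["start"] < prev_end).fillna(False)).any():
        bad = df.index[(df["start"] < prev_end).fillna(False)][0]
        raise MalformedRecordError(
            f"{path}: overlapping spans near {df.at[bad, 'chrom']}:{df.at[bad, 'start']}"
        )
    frags = df[["chrom", "start", "end"]].copy()
    frags["id"] = np.arange(len(frags), dtype=np.int64)
    call = StateCall(
        df["state"].to_numpy(dtype=np.int8), np.zeros(len(df), dtype=bool)
    )
    return frags, call


def write_state_bed(
    call: StateCall, fragments: pd.DataFrame, path: str | Path
) -> None:
    """BED mirror of a state call with state names in the name column."""
    names = call.names()
    keep = ~call.missing
    pd.DataFrame(
        {
            "chrom": fragments["chrom"].to_numpy()[keep],
            "start": fragments["start"].to_numpy()[keep],
            "end": fragments["end"].to_numpy()[keep],
            "name": names[keep],
        }
    ).to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# manifest


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
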