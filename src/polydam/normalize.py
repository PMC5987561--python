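"""Dam-normalized log2 binding profiles.

The binding intensity of a fusion-protein DamID sample at a fragment is the
log2 ratio of its reads-per-million signal over the Dam-only control, with a
pseudocount on the RPM scale:

    value_i = log2( (pc_i/N_pc * 1e6 + c) / (dam_i/N_dam * 1e6 + c) )

Replicates are normalized separately, fragments with highly discordant
values between replicates are excluded by a robust z-score on the replicate
difference, and the surviving fragments carry the arithmetic mean of the
replicate values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import EmptyLibraryError, TooFewFragmentsError
from .fragments import FragmentCounts

DEFAULT_PSEUDOCOUNT = 0.5  # RPM units
DEFAULT_DISCORDANCE_K = 3.0
MAD_TO_SD = 1.4826  # consistency factor for a normal distribution


@dataclass
class NormalizedProfile:
    """Per-fragment Dam-normalized log2 intensity with an exclusion mask.

    ``mask[i]`` True means fragment ``i`` is excluded; ``values[i]`` is NaN
    there and finite everywhere else.
    """

    values: np.ndarray
    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask must have the same shape")
        self.values = np.where(self.mask, np.nan, self.values)
        if not np.isfinite(self.values[~self.mask]).all():
            raise ValueError("unmasked values must be finite")

    @property
    def n_unmasked(self) -> int:
        return int((~self.mask).sum())


def normalize_replicate(
    pc: FragmentCounts, dam: FragmentCounts, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> np.ndarray:
    """log2 RPM ratio of a Dam-fusion sample over its Dam-only control."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if pc.total == 0:
        raise EmptyLibraryError(f"sample {pc.sample}/{pc.replicate} has zero reads")
    if dam.total == 0:
        raise EmptyLibraryError(f"sample {dam.sample}/{dam.replicate} has zero reads")
    if pc.counts.shape != dam.counts.shape:
        raise ValueError("count tables must share the fragment universe")
    rpm_pc = pc.counts / pc.total * 1e6
    rpm_dam = dam.counts / dam.total * 1e6
    return np.log2((rpm_pc + pseudocount) / (rpm_dam + pseudocount))


def exclude_discordant(
    rep1: np.ndarray, rep2: np.ndarray, k: float = DEFAULT_DISCORDANCE_K
) -> np.ndarray:
    """Mask fragments whose replicate difference is a robust outlier.

    Let d = rep1 - rep2.  A fragment is masked iff
    ``|d - median(d)| > k * 1.4826 * MAD(d)``.  With a MAD of zero any
    nonzero deviation from the median is masked.

    Raises
    ------
    TooFewFragmentsError
        If fewer than 10 fragments would survive.
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    rep1 = np.asarray(rep1, dtype=float)
    rep2 = np.asarray(rep2, dtype=float)
    if rep1.shape != rep2.shape:
        raise ValueError("replicates must share the fragment universe")
    d = rep1 - rep2
    med = np.median(d)
    sd = MAD_TO_SD * np.median(np.abs(d - med))
    mask = np.abs(d - med) > k * sd
    if (~mask).sum() < 10:
        raise TooFewFragmentsError(
            f"only {(~mask).sum()} fragments survive discordance exclusion"
        )
    return mask


def average_replicates(
    replicate_values: Sequence[np.ndarray],
    mask: np.ndarray | None = None,
    provenance: dict | None = None,
) -> NormalizedProfile:
    """Average per-replicate values into a NormalizedProfile."""
    if len(replicate_values) == 0:
        raise ValueError("need at least one replicate")
    stack = np.vstack([np.asarray(v, dtype=float) for v in replicate_values])
    mean = stack.mean(axis=0)
    if mask is None:
        mask = np.zeros(mean.shape, dtype=bool)
    return NormalizedProfile(mean, np.asarray(mask, bool), provenance or {})


def normalize_condition(
    pc_reps: Sequence[FragmentCounts],
    dam_reps: Sequence[FragmentCounts],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    discordance_k: float = DEFAULT_DISCORDANCE_K,
) -> NormalizedProfile:
    """Full per-condition normalization: ratio, discordance mask, average.

    Fragments with zero Dam-control counts in every replicate are masked as
    unobserved.  With exactly two replicates the discordance exclusion is
    applied; with one replicate the values pass through unchanged.
    """
    if len(pc_reps) != len(dam_reps) or not pc_reps:
        raise ValueError("need matched, non-empty Dam-fusion and Dam replicate lists")
    values = [normalize_replicate(p, d, pseudocount) for p, d in zip(pc_reps, dam_reps)]
    unobserved = np.all([d.counts == 0 for d in dam_reps], axis=0)
    if len(values) >= 2:
        discord = np.zeros_like(unobserved)
        for i in range(len(values)):
            for j in range(i + 1, len(values)):
                discord |= exclude_discordant(values[i], values[j], discordance_k)
        mask = unobserved | discord
    else:
        mask = unobserved
    prov = {
        "samples": [f"{p.sample}/{p.replicate}" for p in pc_reps]
        + [f"{d.sample}/{d.replicate}" for d in dam_reps],
        "pseudocount": pseudocount,
        "discordance_k": discordance_k,
    }
    return average_replicates(values, mask, prov)
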