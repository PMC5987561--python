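"""Profile-level quality control.

Pearson correlation matrices over jointly unmasked fragments, hierarchical
clustering of profiles (average linkage on 1 - r), lag-k autocorrelation
over neighbouring GATC fragments, and state-specific fragment-size
summaries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .errors import TooFewFragmentsError, UndefinedStatisticError
from .hmm import STATE_NAMES, StateCall
from .normalize import NormalizedProfile


def pearson_matrix(profiles: dict[str, NormalizedProfile]) -> pd.DataFrame:
    """Pairwise Pearson r over the jointly unmasked fragment set."""
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    names = list(profiles)
    joint = ~np.logical_or.reduce([profiles[n].mask for n in names])
    if joint.sum() < 3:
        raise TooFewFragmentsError("fewer than 3 jointly unmasked fragments")
    data = np.vstack([profiles[n].values[joint] for n in names])
    sds = data.std(axis=1)
    for name, sd in zip(names, sds):
        if sd == 0:
            raise UndefinedStatisticError(f"profile {name!r} has zero variance")
    r = np.corrcoef(data)
    return pd.DataFrame(r, index=names, columns=names)


def cluster_profiles(matrix: pd.DataFrame) -> np.ndarray:
    """Agglomerative clustering of profiles with distance 1 - r.

    Returns the scipy linkage matrix (merge list with heights), average
    linkage; scipy's deterministic index-order tie-breaking applies.
    """
    d = 1.0 - matrix.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)  # symmetrize rounding noise
    return linkage(squareform(d, checks=False), method="average")


def dendrogram_newick(merges: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree string."""
    n = len(labels)
    nodes: dict[int, tuple[str, float]] = {i: (labels[i], 0.0) for i in range(n)}
    for i, (a, b, h, _) in enumerate(merges):
        la, ha = nodes[int(a)]
        lb, hb = nodes[int(b)]
        nodes[n + i] = (
            f"({la}:{h - ha:.6g},{lb}:{h - hb:.6g})",
            float(h),
        )
    return nodes[n + len(merges) - 1][0] + ";"


def lag_autocorrelation(
    profile: NormalizedProfile, fragments: pd.DataFrame, lag: int
) -> float:
    """Pearson correlation of values k fragments apart, within chromosomes.

    The lag is in fragment index over consecutive *unmasked* fragments
    (adjacency of recovered GATC sites, not base pairs); pairs never span a
    chromosome boundary; pairs are pooled across chromosomes before the
    correlation is taken.  Lag 0 returns 1 for any non-constant profile.
    """
    if lag < 0:
        raise ValueError("lag must be non-negative")
    xs, ys = [], []
    fragments = fragments.reset_index(drop=True)
    for _, sub in fragments.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        vals = profile.values[idx][~profile.mask[idx]]
        if len(vals) >= lag + 2 or (lag == 0 and len(vals) >= 2):
            xs.append(vals[: len(vals) - lag])
            ys.append(vals[lag:])
    if not xs:
        raise UndefinedStatisticError("no chromosome contributes enough pairs")
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if x.std() == 0 or y.std() == 0:
        raise UndefinedStatisticError("zero variance; autocorrelation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def state_fragment_sizes(call: StateCall, fragments: pd.DataFrame) -> pd.DataFrame:
    """Fragment-length summary (count, median, quartiles) per binding state."""
    lengths = (fragments["end"] - fragments["start"]).to_numpy()
    rows = []
    for code, name in enumerate(STATE_NAMES):
        sel = (~call.missing) & (call.states == code)
        ls = lengths[sel]
        rows.append(
            {
                "state": name,
                "n": int(sel.sum()),
                "median": float(np.median(ls)) if ls.size else np.nan,
                "q1": float(np.percentile(ls, 25)) if ls.size else np.nan,
                "q3": float(np.percentile(ls, 75)) if ls.size else np.nan,
            }
        )
    return pd.DataFrame(rows)


def state_fragment_size_values(
    call: StateCall, fragments: pd.DataFrame
) -> dict[str, np.ndarray]:
    """Full per-state length distributions, exportable for plotting."""
    lengths = (fragments["end"] - fragments["start"]).to_numpy()
    return {
        name: lengths[(~call.missing) & (call.states == code)]
        for code, name in enumerate(STATE_NAMES)
    }
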