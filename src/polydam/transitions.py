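"""Fragment-wise comparison of binding-state calls between two conditions.

Each GATC fragment unmasked in *both* conditions is labelled ``gain``,
``loss`` or ``no_change``; fragments not recovered in either condition are
excluded for both.  Two modes:

* ``full`` — rank-based over depleted(0) < intermediate(1) < enriched(2):
  gain iff the test condition ranks higher than the reference, loss iff
  lower.
* ``enriched_only`` — conservative: only transitions in and out of the
  'enriched' state count; everything else is no_change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError, UndefinedStatisticError
from .hmm import StateCall

LABELS = ("loss", "no_change", "gain")  # codes -1, 0, +1
LABEL_CODE = {"loss": -1, "no_change": 0, "gain": 1}
#: states counted as "bound" for turnover rates
BOUND_STATES = (1, 2)  # intermediate, enriched


@dataclass
class TransitionCall:
    """Per-fragment gain/loss/no-change labels for a condition pair.

    ``labels[i]`` in {-1 loss, 0 no_change, +1 gain}; ``defined[i]`` False
    where either condition was masked.
    """

    labels: np.ndarray  # int8, -1/0/+1
    defined: np.ndarray  # bool
    mode: str = "full"
    pair: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.defined = np.asarray(self.defined, dtype=bool)
        if self.labels.shape != self.defined.shape:
            raise ValueError("labels and defined must share shape")

    def names(self) -> np.ndarray:
        out = np.full(self.labels.shape, None, dtype=object)
        nm = np.array(LABELS, dtype=object)
        out[self.defined] = nm[self.labels[self.defined] + 1]
        return out


def compare_states(a: StateCall, b: StateCall, mode: str = "full") -> TransitionCall:
    """Label each jointly unmasked fragment gain/loss/no_change (B vs A)."""
    if a.states.shape != b.states.shape:
        raise AlignmentError("state calls live on different fragment universes")
    if mode not in ("full", "enriched_only"):
        raise ValueError(f"unknown mode {mode!r}")
    defined = ~(a.missing | b.missing)
    labels = np.zeros(a.states.shape, dtype=np.int8)
    sa = a.states.astype(np.int8)
    sb = b.states.astype(np.int8)
    if mode == "full":
        labels[defined & (sb > sa)] = 1
        labels[defined & (sb < sa)] = -1
    else:
        labels[defined & (sb == 2) & (sa != 2)] = 1
        labels[defined & (sa == 2) & (sb != 2)] = -1
    return TransitionCall(labels, defined, mode)


def summarize_transitions(
    t: TransitionCall, fragments: pd.DataFrame, group_by: str = "genome"
) -> pd.DataFrame:
    """Percent gain/loss/no_change per chromosome or genome-wide.

    Returns a table with columns ``group, n, pct_gain, pct_loss,
    pct_no_change``; percentages per row sum to 100.
    """
    if not t.defined.any():
        raise UndefinedStatisticError("transition call defines no fragments")
    df = pd.DataFrame(
        {
            "chrom": fragments["chrom"].to_numpy()[t.defined],
            "label": t.labels[t.defined],
        }
    )
    if group_by == "genome":
        df["group"] = "genome"
    elif group_by == "chromosome":
        df["group"] = df["chrom"]
    else:
        raise ValueError("group_by must be 'chromosome' or 'genome'")
    rows = []
    for g, sub in df.groupby("group", sort=True):
        n = len(sub)
        rows.append(
            {
                "group": g,
                "n": n,
                "pct_gain": 100.0 * (sub["label"] == 1).sum() / n,
                "pct_loss": 100.0 * (sub["label"] == -1).sum() / n,
                "pct_no_change": 100.0 * (sub["label"] == 0).sum() / n,
            }
        )
    return pd.DataFrame(rows)


def bound_state_turnover(a: StateCall, b: StateCall) -> dict[str, float]:
    """Percent of bound states lost, and arising de novo, between conditions.

    "Bound" pools the intermediate and enriched states.  ``pct_lost`` is the
    share of fragments bound in the reference that are labelled loss under
    the full-mode comparison; ``pct_de_novo`` is the share of fragments
    bound in the test condition whose reference state was outside the bound
    set (i.e. newly bound).
    """
    t = compare_states(a, b, mode="full")
    d = t.defined
    bound_a = d & np.isin(a.states, BOUND_STATES) & ~a.missing
    bound_b = d & np.isin(b.states, BOUND_STATES) & ~b.missing
    if bound_a.sum() == 0 or bound_b.sum() == 0:
        raise UndefinedStatisticError("no bound fragments in a denominator condition")
    lost = bound_a & (t.labels == -1)
    de_novo = bound_b & (t.labels == 1) & ~np.isin(a.states, BOUND_STATES)
    return {
        "pct_lost": 100.0 * lost.sum() / bound_a.sum(),
        "pct_de_novo": 100.0 * de_novo.sum() / bound_b.sum(),
    }


def cross_tabulate_transitions(t1: TransitionCall, t2: TransitionCall) -> pd.DataFrame:
    """3x3 contingency of labels across two comparisons (shared universe)."""
    if t1.labels.shape != t2.labels.shape:
        raise AlignmentError("transition calls live on different fragment universes")
    both = t1.defined & t2.defined
    tab = pd.DataFrame(
        0, index=list(LABELS), columns=list(LABELS), dtype=np.int64
    )
    for l1 in (-1, 0, 1):
        for l2 in (-1, 0, 1):
            tab.loc[LABELS[l1 + 1], LABELS[l2 + 1]] = int(
                (both & (t1.labels == l1) & (t2.labels == l2)).sum()
            )
    tab.index.name = "comparison1"
    tab.columns.name = "comparison2"
    return tab
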