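"""Synthetic DamID-seq data with the statistical structure the pipeline assumes.

The generator emulates, per configuration:

* a random genome with GATC motifs planted as a Poisson process, giving the
  uneven fragment-length distribution DpnI digestion produces;
* a hidden three-state binding path drawn from the same distance-dependent
  transition kernel the HMM fits (``p0 = 1`` by default, so zero-distance
  neighbours always agree and the L -> infinity limit is a single state per
  chromosome);
* per-fragment true log2 enrichment ``state_mean + N(0, state_sd)`` shared
  across replicates, turned into overdispersed Dam / Dam-fusion counts via
  a gamma–Poisson (negative binomial) model with mean proportional to
  fragment length;
* a differential-expression table with exact up/down allocations so the
  adjusted-p filter downstream is exercised.

Every operation is deterministic given ``SimConfig.seed``; each draws from
its own seeded stream so operations are reproducible independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, OrderingError
from .fragments import FragmentCounts
from .hmm import HMMParams, _transition_stack
from .normalize import NormalizedProfile

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# per-operation stream ids so each op is independently reproducible
_STREAM = {"genome": 1, "states": 2, "counts": 3, "de": 4, "emissions": 5, "perturb": 6}


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator."""

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 250_000  # bases
    gatc_rate: float = 4.0  # expected planted motifs per kb
    state_means: tuple[float, float, float] = (-1.5, 0.0, 1.5)  # log2 units
    state_sd: float = 0.5  # log2 units
    stationary: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    decay_length: float = 2000.0  # bases
    p0: float = 1.0  # zero-distance self-transition of the hidden chain
    dam_mean_per_kb: float = 150.0  # expected Dam reads per kb of fragment
    dispersion: float = 20.0  # NB size; inf = Poisson
    n_replicates: int = 2
    n_genes: int = 200
    frac_up: float = 0.15
    frac_down: float = 0.15
    change_rate: float = 0.15  # per-segment state-change rate between conditions
    tss_margin: int = 4000  # keep TSS windows clear of chromosome ends

    def __post_init__(self) -> None:
        if self.chrom_length <= 0 or self.n_chroms <= 0:
            raise ConfigError("chromosome count and length must be positive")
        if not np.all(np.diff(self.state_means) > 0):
            raise ConfigError("state_means must be strictly ascending")
        if self.state_sd <= 0:
            raise ConfigError("state_sd must be positive")
        if abs(sum(self.stationary) - 1.0) > 1e-9 or min(self.stationary) <= 0:
            raise ConfigError("stationary must be positive and sum to 1")
        if self.gatc_rate < 0 or self.dam_mean_per_kb <= 0 or self.decay_length <= 0:
            raise ConfigError("rates must be positive (gatc_rate may be zero)")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be positive")
        if self.frac_up < 0 or self.frac_down < 0 or self.frac_up + self.frac_down > 1:
            raise ConfigError("frac_up + frac_down must lie in [0, 1]")

    def hmm_params(self) -> HMMParams:
        """The generator's hidden chain as HMM parameters."""
        return HMMParams(
            mu=np.array(self.state_means),
            sigma=np.full(3, self.state_sd),
            pi=np.array(self.stationary),
            p0=self.p0,
            L=self.decay_length,
        )


def _rng(cfg: SimConfig, op: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, _STREAM[op], extra])


def simulate_genome(cfg: SimConfig) -> dict[str, str]:
    """Random A/C/G/T chromosomes with GATC motifs planted at `gatc_rate`/kb."""
    rng = _rng(cfg, "genome")
    genome: dict[str, str] = {}
    for i in range(cfg.n_chroms):
        seq = _BASES[rng.integers(0, 4, cfg.chrom_length)].copy()
        n_motifs = rng.poisson(cfg.gatc_rate * cfg.chrom_length / 1000.0)
        if n_motifs > 0 and cfg.chrom_length >= 4:
            pos = np.sort(rng.integers(0, cfg.chrom_length - 3, n_motifs))
            keep = np.concatenate([[True], np.diff(pos) >= 4])
            for p in pos[keep]:
                seq[p : p + 4] = _BASES[[2, 0, 3, 1]]  # G A T C
        genome[f"chr{i + 1}"] = seq.tobytes().decode("ascii")
    return genome


def simulate_states(fragments: pd.DataFrame, cfg: SimConfig) -> np.ndarray:
    """Hidden state per fragment from the distance-dependent chain."""
    rng = _rng(cfg, "states")
    pi = np.array(cfg.stationary)
    states = np.zeros(len(fragments), dtype=np.int8)
    fragments = fragments.reset_index(drop=True)
    for _, sub in fragments.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        if np.any(np.diff(starts) < 0):
            raise OrderingError("fragments must be sorted within chromosome")
        idx = sub.index.to_numpy()
        mid = (starts + sub["end"].to_numpy()) / 2.0
        A = _transition_stack(np.diff(mid), pi, cfg.p0, cfg.decay_length)
        u = rng.random(len(idx))
        s = int(np.searchsorted(np.cumsum(pi), u[0]))
        states[idx[0]] = s
        for t in range(1, len(idx)):
            s = int(np.searchsorted(np.cumsum(A[t - 1, s]), u[t]))
            s = min(s, 2)
            states[idx[t]] = s
    return states


def perturb_states(
    states: np.ndarray, fragments: pd.DataFrame, cfg: SimConfig
) -> np.ndarray:
    """Second-condition state path: loci-specific changes to segments.

    Each maximal same-state run is, with probability ``change_rate``,
    reassigned to one of the two other states (uniformly); otherwise kept.
    This emulates binding-state turnover concentrated at a subset of loci
    rather than genome-wide reshuffling.
    """
    rng = _rng(cfg, "perturb")
    out = np.asarray(states, dtype=np.int8).copy()
    chrom = fragments["chrom"].to_numpy()
    boundaries = np.flatnonzero(
        np.concatenate([[True], (out[1:] != out[:-1]) | (chrom[1:] != chrom[:-1])])
    )
    segment_ends = np.concatenate([boundaries[1:], [len(out)]])
    for s, e in zip(boundaries, segment_ends):
        if rng.random() < cfg.change_rate:
            others = [k for k in (0, 1, 2) if k != out[s]]
            out[s:e] = others[rng.integers(0, 2)]
    return out


def _nb(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma–Poisson (negative binomial, size = dispersion) counts."""
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-9)
    if np.isinf(dispersion):
        return rng.poisson(mean)
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion)
    return rng.poisson(lam)


def simulate_counts(
    fragments: pd.DataFrame, true_states: np.ndarray, cfg: SimConfig
) -> dict[str, list[FragmentCounts]]:
    """Dam and Dam-fusion count tables for each replicate.

    Dam counts have mean ``dam_mean_per_kb * length/1000``; fusion counts
    multiply that by ``2 ** (state_mean + N(0, state_sd))``, the jitter
    shared across replicates (it is part of the per-fragment truth, not
    sequencing noise).  Replicates are conditionally i.i.d.
    """
    rng = _rng(cfg, "counts")
    n = len(fragments)
    if n == 0:
        return {"dam": [], "pc": []}
    lengths = (fragments["end"] - fragments["start"]).to_numpy()
    dam_mean = cfg.dam_mean_per_kb * lengths / 1000.0
    means = np.asarray(cfg.state_means)
    log_ratio = means[np.asarray(true_states)] + rng.normal(0, cfg.state_sd, n)
    pc_mean = dam_mean * np.exp2(log_ratio)
    out: dict[str, list[FragmentCounts]] = {"dam": [], "pc": []}
    for r in range(cfg.n_replicates):
        out["dam"].append(
            FragmentCounts("dam", str(r + 1), _nb(rng, dam_mean, cfg.dispersion))
        )
        out["pc"].append(
            FragmentCounts("pc", str(r + 1), _nb(rng, pc_mean, cfg.dispersion))
        )
    return out


def simulate_emissions(
    fragments: pd.DataFrame, true_states: np.ndarray, cfg: SimConfig
) -> NormalizedProfile:
    """Profile drawn from the HMM's own Gaussian emission model.

    This is the count-free fixture for parameter-recovery checks: values
    are exactly ``N(state_mean, state_sd)`` with no library-size effects.
    """
    rng = _rng(cfg, "emissions")
    means = np.asarray(cfg.state_means)
    vals = means[np.asarray(true_states)] + rng.normal(
        0, cfg.state_sd, len(true_states)
    )
    return NormalizedProfile(vals, np.zeros(len(vals), dtype=bool), {"source": "sim"})


def simulate_de_table(cfg: SimConfig, chrom_sizes: dict[str, int]) -> pd.DataFrame:
    """Gene table with TSS, strand and DE columns.

    Exactly ``round(frac_up * n_genes)`` genes are significantly up
    (log2FC > 0, padj < 0.05), ``round(frac_down * n_genes)`` down, the
    rest non-significant.  TSSs are uniform within chromosomes, kept
    ``tss_margin`` away from the ends.
    """
    rng = _rng(cfg, "de")
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    for c, s in zip(chroms, sizes):
        if s <= 2 * cfg.tss_margin:
            raise ConfigError(f"chromosome {c} too short for tss_margin={cfg.tss_margin}")
    probs = sizes / sizes.sum()
    n = cfg.n_genes
    chrom_idx = rng.choice(len(chroms), size=n, p=probs)
    tss = np.array(
        [
            rng.integers(cfg.tss_margin, chrom_sizes[chroms[i]] - cfg.tss_margin)
            for i in chrom_idx
        ]
    )
    strand = np.where(rng.random(n) < 0.5, "+", "-")
    n_up = round(cfg.frac_up * n)
    n_down = round(cfg.frac_down * n)
    log2fc = np.empty(n)
    padj = np.empty(n)
    log2fc[:n_up] = rng.uniform(0.5, 3.0, n_up)
    log2fc[n_up : n_up + n_down] = -rng.uniform(0.5, 3.0, n_down)
    log2fc[n_up + n_down :] = rng.normal(0.0, 0.2, n - n_up - n_down)
    padj[: n_up + n_down] = rng.uniform(1e-6, 0.049, n_up + n_down)
    padj[n_up + n_down :] = rng.uniform(0.05, 1.0, n - n_up - n_down)
    return pd.DataFrame(
        {
            "gene": [f"gene{i + 1:04d}" for i in range(n)],
            "chrom": [chroms[i] for i in chrom_idx],
            "tss": tss,
            "strand": strand,
            "log2fc": log2fc,
            "padj": padj,
        }
    )
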