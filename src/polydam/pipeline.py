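"""End-to-end orchestration: counts -> profiles -> states -> transitions -> groups.

``run_pipeline`` drives the whole analysis for a reference and a test
condition and writes every output plus a machine-readable manifest.  Inputs
come either from files (count tables, gene annotation, DE table) or from
the synthetic generator; in synthetic mode the manifest additionally
reports state-recovery accuracy against the simulated truth.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from . import qc as pqc
from .errors import PolydamError
from .fragments import FragmentCounts, find_gatc_fragments
from .hmm import FitConfig, HMMFit, fit_em
from .normalize import (
    DEFAULT_DISCORDANCE_K,
    DEFAULT_PSEUDOCOUNT,
    NormalizedProfile,
    normalize_condition,
)
from .regulatory import DEFAULT_DOWNSTREAM, DEFAULT_UPSTREAM, integrate
from .simulate import SimConfig, perturb_states, simulate_counts, simulate_de_table, simulate_genome, simulate_states
from .transitions import bound_state_turnover, compare_states, summarize_transitions

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of the pipeline with their documented defaults."""

    seed: int = 0
    outdir: str = "polydam_out"
    # normalization
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    discordance_k: float = DEFAULT_DISCORDANCE_K
    # HMM
    hmm_tol: float = 1e-6
    hmm_max_iter: int = 500
    hmm_var_floor: float = 1e-3
    # transitions
    transition_mode: str = "full"
    # regulatory integration
    window_upstream: int = DEFAULT_UPSTREAM
    window_downstream: int = DEFAULT_DOWNSTREAM
    padj_threshold: float = 0.05
    # synthetic-mode generator settings (ignored in file mode)
    sim: dict = field(default_factory=dict)
    # file-mode inputs: condition -> {"dam": [paths], "pc": [paths]}
    counts: dict = field(default_factory=dict)
    genome: str | None = None
    genes: str | None = None
    de: str | None = None

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except PolydamError as exc:
                raise type(exc)(f"[stage {name}] {exc}") from exc
            log.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
            return out

        return inner

    return wrap


@_stage("hmm")
def fit_condition(
    profile: NormalizedProfile, fragments: pd.DataFrame, cfg: RunConfig
) -> HMMFit:
    return fit_em(
        profile,
        fragments,
        config=FitConfig(
            tol=cfg.hmm_tol, max_iter=cfg.hmm_max_iter, var_floor=cfg.hmm_var_floor
        ),
    )


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis and write all outputs under ``cfg.outdir``.

    Returns the result bundle: fragments, per-condition profiles and HMM
    fits, the transition call and summaries, the per-gene group table, QC
    metrics, and the manifest dict.  Deterministic given config and seed.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    synthetic = not cfg.counts

    truth: dict[str, np.ndarray] = {}
    if synthetic:
        sim = SimConfig(seed=cfg.seed, **cfg.sim)
        genome = simulate_genome(sim)
        fragments = find_gatc_fragments(genome)
        states_a = simulate_states(fragments, sim)
        states_b = perturb_states(states_a, fragments, sim)
        truth = {"reference": states_a, "test": states_b}
        counts = {
            "reference": simulate_counts(fragments, states_a, sim),
            "test": simulate_counts(fragments, states_b, dataclasses.replace(sim, seed=sim.seed + 1)),
        }
        chrom_sizes = {c: len(s) for c, s in genome.items()}
        gene_table = simulate_de_table(sim, chrom_sizes)
        pio.write_fasta(genome, outdir / "genome.fa")
        pd.DataFrame({"fragment_id": fragments["id"], "state_reference": states_a, "state_test": states_b}).to_csv(
            outdir / "truth_states.tsv", sep="\t", index=False
        )
    else:
        genome = pio.read_fasta(cfg.genome)
        fragments = find_gatc_fragments(genome)
        chrom_sizes = {c: len(s) for c, s in genome.items()}
        counts = {}
        for cond, paths in cfg.counts.items():
            counts[cond] = {
                kind: [
                    pio.read_counts_tsv(p, sample=f"{cond}_{kind}", replicate=str(i + 1))[1]
                    for i, p in enumerate(paths[kind])
                ]
                for kind in ("dam", "pc")
            }
        gene_table = pio.read_gene_table(cfg.genes)
        de = pio.read_de_table(cfg.de)
        gene_table = gene_table.merge(de, on="gene", how="inner")

    pio.write_fragments_bed(fragments, outdir / "fragments.bed")

    profiles: dict[str, NormalizedProfile] = {}
    fits: dict[str, HMMFit] = {}
    for cond in counts:
        profiles[cond] = normalize_condition(
            counts[cond]["pc"],
            counts[cond]["dam"],
            pseudocount=cfg.pseudocount,
            discordance_k=cfg.discordance_k,
        )
        pio.write_profile_tsv(profiles[cond], fragments, outdir / f"profile_{cond}.tsv")
        fits[cond] = fit_condition(profiles[cond], fragments, cfg)
        pio.write_state_wig(
            fits[cond].viterbi, fragments, outdir / f"states_{cond}.wig", name=cond
        )
        pio.write_state_bed(fits[cond].viterbi, fragments, outdir / f"states_{cond}.bed")

    conds = list(counts)
    ref, test = conds[0], conds[1] if len(conds) > 1 else conds[0]
    tcall = compare_states(fits[ref].viterbi, fits[test].viterbi, cfg.transition_mode)
    summary_genome = summarize_transitions(tcall, fragments, "genome")
    summary_chrom = summarize_transitions(tcall, fragments, "chromosome")
    pd.concat([summary_chrom, summary_genome]).to_csv(
        outdir / "transition_summary.tsv", sep="\t", index=False
    )
    turnover = bound_state_turnover(fits[ref].viterbi, fits[test].viterbi)

    groups = integrate(
        gene_table[["gene", "log2fc", "padj"]],
        gene_table[["gene", "chrom", "tss", "strand"]],
        fragments,
        tcall,
        chrom_sizes,
        upstream=cfg.window_upstream,
        downstream=cfg.window_downstream,
        padj_threshold=cfg.padj_threshold,
    )
    groups.to_csv(outdir / "gene_groups.tsv", sep="\t", index=False)
    for g, sub in groups.groupby("group"):
        if g != "none":
            sub["gene"].to_csv(outdir / f"genes_group_{g}.txt", index=False, header=False)

    corr = pqc.pearson_matrix(profiles) if len(profiles) > 1 else None
    qc_metrics: dict = {}
    if corr is not None:
        corr.to_csv(outdir / "profile_correlations.tsv", sep="\t")
        qc_metrics["pearson"] = corr.to_dict()
    try:
        qc_metrics["lag2_autocorrelation"] = {
            cond: pqc.lag_autocorrelation(profiles[cond], fragments, 2)
            for cond in profiles
        }
    except PolydamError:
        pass
    sizes = {cond: pqc.state_fragment_sizes(fits[cond].viterbi, fragments) for cond in fits}
    pd.concat(sizes, names=["condition"]).to_csv(outdir / "state_fragment_sizes.tsv", sep="\t")

    manifest: dict = {
        "package": "polydam",
        "seed": cfg.seed,
        "parameters": dataclasses.asdict(cfg),
        "conditions": conds,
        "n_fragments": int(len(fragments)),
        "hmm": {
            cond: {
                "mu": fits[cond].params.mu.tolist(),
                "sigma": fits[cond].params.sigma.tolist(),
                "pi": fits[cond].params.pi.tolist(),
                "p0": fits[cond].params.p0,
                "L": fits[cond].params.L,
                "converged": fits[cond].converged,
                "degenerate": fits[cond].degenerate,
                "n_iterations": len(fits[cond].loglik_trace) - 1,
            }
            for cond in fits
        },
        "transitions": summary_genome.iloc[0].to_dict(),
        "turnover": turnover,
        "group_counts": groups["group"].value_counts().to_dict(),
        "qc": qc_metrics,
    }
    if truth:
        manifest["state_recovery_accuracy"] = {
            cond: _accuracy(fits[cond].viterbi, truth[cond]) for cond in truth
        }
    pio.write_manifest(manifest, outdir / "manifest.json")
    RunConfig(**dataclasses.asdict(cfg)).to_yaml(outdir / "config.yaml")

    return {
        "fragments": fragments,
        "profiles": profiles,
        "fits": fits,
        "transitions": tcall,
        "summary": summary_genome,
        "turnover": turnover,
        "groups": groups,
        "manifest": manifest,
        "truth": truth,
    }


def _accuracy(call, truth: np.ndarray) -> float:
    keep = ~call.missing
    if keep.sum() == 0:
        return float("nan")
    return float((call.states[keep] == truth[keep]).mean())
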