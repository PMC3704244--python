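"""The two-stage admixture-mapping procedure.

Stage 1 screens one locus at a time: fit y ~ 1 + S_j + E per locus (per
imputation draw when the local ancestries are multiply imputed), convert
the fit to a QNM Bayes factor with the empirical-Bayes tau, average the
Bayes factors over draws, and select the loci with log10 BF above the
threshold delta (default 2).

Stage 2 quantifies joint evidence: every non-empty subset of the selected
loci (up to a cardinality cap) is fitted jointly and scored by the joint
Bayes factor with p = |subset|.  Subsets are ranked by log10 BF, ties
broken in favor of smaller subsets then lexicographic locus order.  The
final identified set is, by default, the membership of the top-ranked
subset that passes delta — one mutually exclusive outcome per run, which is
what makes the reported locus/locus-pair frequencies add up.

With at most one selected locus stage 2 is unnecessary and the stage-1
selection is reported as identified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from ._scan import single_locus_stats
from .ancestry_sim import AncestryPanel
from .bayes_factor import (
    BFResult,
    EBEstimates,
    _maximize_over_t,
    average_bf,
    eb_log10bf_scan,
    log_qnm_bf,
    qnm_bayes_factor,
)
from .glm_core import (
    DegenerateDesignError,
    SeparationError,
    TraitVector,
    build_design,
    extract_ancestry_block,
    fit_glm,
)

__all__ = [
    "ScanConfig",
    "LocusResult",
    "SubsetResult",
    "MappingReport",
    "CombinatorialCapError",
    "stage1_scan",
    "stage2_joint",
    "identify",
    "run_gleam",
]


class CombinatorialCapError(RuntimeError):
    """Too many stage-1 selections to enumerate subsets.

    Raise the selection threshold delta or the caps to proceed.
    """


@dataclass
class ScanConfig:
    """Configuration of a mapping run."""

    delta: float = 2.0
    family: str = "gaussian"
    tau_mode: str = "per_locus"  # or "genomewide"
    max_selected: int = 15
    max_subset_size: int = 10
    identify_rule: str = "top_subset"  # or "all_passing"
    seed: int | None = None

    def __post_init__(self):
        if self.max_selected < 1 or self.max_subset_size < 1:
            raise ValueError("caps must be >= 1")
        if self.tau_mode not in ("per_locus", "genomewide"):
            raise ValueError("tau_mode must be 'per_locus' or 'genomewide'")


@dataclass
class LocusResult:
    locus: int
    locus_id: str
    beta_hat: float
    se: float
    log10_bf: float
    selected: bool
    skipped_reason: str = ""


@dataclass
class SubsetResult:
    loci: tuple
    log10_bf: float
    rank: int = 0


@dataclass
class MappingReport:
    stage1: list
    selected: list
    stage2: list
    identified: list
    config: ScanConfig
    tau_hat: float
    eb: EBEstimates | None = None

    def stage1_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"locus": r.locus, "locus_id": r.locus_id, "beta_hat": r.beta_hat,
              "se": r.se, "log10_bf": r.log10_bf, "selected": r.selected,
              "skipped_reason": r.skipped_reason} for r in self.stage1]
        )

    def stage2_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"rank": s.rank, "loci": "+".join(str(l) for l in s.loci),
              "log10_bf": s.log10_bf} for s in self.stage2],
            columns=["rank", "loci", "log10_bf"],
        )


def _align(panel: AncestryPanel, y: TraitVector, E):
    if len(y) != panel.n_subjects:
        raise ValueError("panel and trait are misaligned on subjects")
    if E is not None:
        E = np.asarray(E, dtype=float)
        if E.ndim == 1:
            E = E.reshape(-1, 1)
        if E.shape[0] != panel.n_subjects:
            raise ValueError("covariates misaligned on subjects")
    return E


def stage1_scan(panel: AncestryPanel, y: TraitVector, E, cfg: ScanConfig
                ) -> tuple[list, EBEstimates]:
    """Single-locus screen over all loci, averaged over imputation draws."""
    E = _align(panel, y, E)
    draws = panel.draws()
    J = panel.n_loci
    I = panel.n_subjects

    bf_draws = np.zeros((len(draws), J))
    beta_draws = np.zeros((len(draws), J))
    se_draws = np.full((len(draws), J), np.nan)
    t_hat_draws = np.zeros((len(draws), J))
    skipped_any = np.zeros(J, dtype=bool)
    reasons = np.full(J, "", dtype=object)

    for m, S in enumerate(draws):
        stats = single_locus_stats(S, y.values, E, family=y.family)
        skipped_any |= stats.skipped
        fresh = (reasons == "") & stats.skipped
        reasons[fresh] = stats.skip_reason[fresh]
        ok = ~stats.skipped
        if cfg.tau_mode == "per_locus":
            log10bf, t_hat = eb_log10bf_scan(stats.wald[ok], p=1)
        else:
            t_hat_g, _ = _maximize_over_t(
                lambda t: float(np.sum(log_qnm_bf(stats.wald[ok], 1, t)))
            )
            log10bf = np.asarray(log_qnm_bf(stats.wald[ok], 1, t_hat_g)) / np.log(10.0)
            t_hat = np.full(ok.sum(), t_hat_g)
        bf_col = np.zeros(J)
        bf_col[ok] = 10.0 ** log10bf
        bf_draws[m] = bf_col
        beta_draws[m] = stats.beta
        se_draws[m, ok] = stats.se[ok]
        t_hat_draws[m, ok] = t_hat

    with np.errstate(divide="ignore"):
        bf_bar = bf_draws.mean(axis=0)
        log10_bar = np.where(bf_bar > 0, np.log10(np.maximum(bf_bar, 1e-300)), -np.inf)
    beta_bar = beta_draws.mean(axis=0)
    se_bar = np.nanmean(se_draws, axis=0)
    tau_per_locus = t_hat_draws.mean(axis=0) / I

    results = []
    ids = panel.meta["locus_id"].tolist()
    for j in range(J):
        sel = (not skipped_any[j]) and (log10_bar[j] > cfg.delta)
        results.append(LocusResult(
            locus=j, locus_id=ids[j], beta_hat=float(beta_bar[j]),
            se=float(se_bar[j]) if np.isfinite(se_bar[j]) else float("nan"),
            log10_bf=float(log10_bar[j]) if not skipped_any[j] else float("nan"),
            selected=bool(sel), skipped_reason=str(reasons[j]),
        ))
    if skipped_any.all():
        raise RuntimeError("all loci were skipped")

    eb = EBEstimates(
        tau_hat=float(tau_per_locus[~skipped_any].mean()),
        per_locus_tau=tau_per_locus,
        mode=cfg.tau_mode,
    )
    return results, eb


def _joint_bf_one_draw(S, y, E, loci, cfg, eb: EBEstimates | None, I) -> BFResult:
    X = build_design(S[:, list(loci)].astype(float), E,
                     labels=[str(l) for l in loci])
    fit = fit_glm(y, X)
    block = extract_ancestry_block(fit)
    p = len(loci)
    if cfg.tau_mode == "genomewide" and eb is not None:
        return qnm_bayes_factor(block, tau=eb.tau_hat, I=I, p=p)
    from .bayes_factor import _quadform

    wald = _quadform(*block)
    t_hat, _ = _maximize_over_t(lambda t: float(log_qnm_bf(wald, p, t)))
    return qnm_bayes_factor(block, tau=t_hat / I, I=I, p=p)


def stage2_joint(panel: AncestryPanel, y: TraitVector, E, selected, cfg: ScanConfig,
                 eb: EBEstimates | None = None) -> list:
    """Joint Bayes factors over all non-empty subsets of the selected loci."""
    E = _align(panel, y, E)
    selected = sorted(selected)
    if len(selected) < 2:
        return []
    if len(selected) > cfg.max_selected:
        raise CombinatorialCapError(
            f"{len(selected)} stage-1 selections exceed max_selected="
            f"{cfg.max_selected}; raise delta or the cap"
        )
    I = panel.n_subjects
    results = []
    for size in range(1, min(len(selected), cfg.max_subset_size) + 1):
        for loci in combinations(selected, size):
            bfs = []
            for S in panel.draws():
                try:
                    bfs.append(_joint_bf_one_draw(S, y, E, loci, cfg, eb, I))
                except (SeparationError, DegenerateDesignError):
                    continue
            if not bfs:
                continue
            avg = average_bf(bfs)
            results.append(SubsetResult(loci=tuple(loci), log10_bf=avg.log10_bf))
    results.sort(key=lambda s: (-s.log10_bf, len(s.loci), s.loci))
    for rank, s in enumerate(results, start=1):
        s.rank = rank
    return results


def identify(report: MappingReport, rule: str | None = None) -> list:
    """Operational rule turning stage results into the identified locus set."""
    rule = rule or report.config.identify_rule
    if len(report.selected) <= 1:
        return list(report.selected)
    passing = [s for s in report.stage2 if s.log10_bf > report.config.delta]
    if not passing:
        return []
    if rule == "top_subset":
        return list(passing[0].loci)
    if rule == "all_passing":
        out = set()
        for s in passing:
            out.update(s.loci)
        return sorted(out)
    raise ValueError(f"unknown identify rule {rule!r}")


def run_gleam(panel: AncestryPanel, y: TraitVector, E, cfg: ScanConfig,
              two_stage: bool = True) -> MappingReport:
    """Run the full procedure and assemble the mapping report.

    ``two_stage=False`` stops after the screen (the stage-1-only variant):
    identified = all loci passing delta.  If stage-1 selections exceed the
    subset cap, the top ``max_selected`` loci by log10 BF are carried into
    stage 2 (noted in the report's config echo semantics; see methods note).
    """
    stage1, eb = stage1_scan(panel, y, E, cfg)
    selected = [r.locus for r in stage1 if r.selected]
    if not two_stage:
        return MappingReport(stage1=stage1, selected=selected, stage2=[],
                             identified=list(selected), config=cfg,
                             tau_hat=eb.tau_hat, eb=eb)
    carried = selected
    if len(selected) > cfg.max_selected:
        order = sorted(selected,
                       key=lambda j: -next(r.log10_bf for r in stage1 if r.locus == j))
        carried = sorted(order[: cfg.max_selected])
    stage2 = stage2_joint(panel, y, E, carried, cfg, eb=eb)
    report = MappingReport(stage1=stage1, selected=selected, stage2=stage2,
                           identified=[], config=cfg, tau_hat=eb.tau_hat, eb=eb)
    report.identified = identify(report)
    return report
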