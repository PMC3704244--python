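"""Synthetic local-ancestry panels and the simulation experiments.

Three generators cover the study designs the mapping method is evaluated
on:

* ``sim_hwe_panel`` — loci in linkage equilibrium, dosages drawn under
  Hardy-Weinberg equilibrium from per-locus high-risk ancestry proportions
  p_a (the null design: 1000 loci x 1000 subjects, p_a ~ U(0.70, 0.90)).
* ``sim_correlated_pair`` — two loci coupled through a latent bivariate
  normal with thresholds C0 = Phi^-1((1-p_a)^2), C1 = Phi^-1(1-p_a^2), so
  each margin is exactly HWE while the latent correlation rho controls the
  admixture LD.
* ``sim_chromosome`` — an artificial chromosome of two pieces (139.50 and
  114.88 Mb, 51 equally spaced loci each, 1 cM/Mb) with block-structured
  ancestry: each haplotype follows a two-state Markov process along the
  genetic map with switch probability 1 - exp(-g d / 100) per d cM, and each
  locus reports the block ancestry with probability ``fidelity`` (else an
  independent HWE draw).  The fidelity layer emulates estimated rather than
  perfectly observed local ancestry; the defaults (g = 0.5, fidelity =
  0.412) were calibrated once so that the loci whose dosage correlation with
  the mid-piece causal locus exceeds 0.12 span each piece the way the
  flanking regions of the two-locus experiment are defined (~39-41 loci per
  piece, ~20 unassociated).  See docs/methods.md for why a pure block
  process cannot satisfy that construction.

Traits come from the GLM with UNcentered dosages and no intercept:
y = alpha E + sum_j beta_j S_j + eps (gaussian) or the logit analogue, with
beta_j = c_j * p_a,j, E and eps standard normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "AncestryPanel",
    "SimDesign",
    "RegionLabels",
    "map_allele_freq",
    "sim_hwe_panel",
    "sim_correlated_pair",
    "sim_chromosome",
    "sim_traits",
    "dichotomize_extremes",
    "classify_regions",
    "run_experiment",
    "null_design",
    "single_locus_design",
    "two_locus_design",
    "artificial_chromosome_map",
]

# calibrated block/fidelity defaults for the artificial chromosome
CHROM_GENERATIONS = 0.25
CHROM_FIDELITY = 0.387
PIECE_LENGTHS_MB = (139.50, 114.88)
LOCI_PER_PIECE = 51
R_THRESHOLD = 0.12


@dataclass
class AncestryPanel:
    """Subjects x loci dosage matrix with locus metadata.

    ``dosage`` holds 0/1/2 copies from the high-risk ancestral population;
    ``meta`` is a DataFrame with columns locus_id, chrom, pos_bp, cM, p_a
    sorted by (chrom, pos_bp).  ``imputations`` optionally holds M sampled
    dosage matrices for multiple-imputation averaging.
    """

    dosage: np.ndarray
    meta: pd.DataFrame
    imputations: list = field(default_factory=list)

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage)
        if not np.all(np.isin(self.dosage, (0, 1, 2))):
            raise ValueError("dosage entries must be 0/1/2")
        need = {"locus_id", "chrom", "pos_bp", "cM", "p_a"}
        if not need.issubset(self.meta.columns):
            raise ValueError(f"metadata missing columns {need - set(self.meta.columns)}")
        if len(self.meta) != self.dosage.shape[1]:
            raise ValueError("metadata rows must match dosage columns")
        key = self.meta[["chrom", "pos_bp"]].apply(tuple, axis=1).tolist()
        if key != sorted(key):
            raise ValueError("loci must be sorted by (chrom, pos_bp)")
        if np.any((self.meta["p_a"] < 0) | (self.meta["p_a"] > 1)):
            raise ValueError("p_a must lie in [0, 1]")

    @property
    def n_subjects(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosage.shape[1]

    def draws(self):
        """Iterate over imputation draws (the point panel if none)."""
        return self.imputations if self.imputations else [self.dosage]


@dataclass
class SimDesign:
    """Full specification of a simulation experiment."""

    family: str = "gaussian"
    n_subjects: int = 1000
    n_loci: int = 1000
    panel_kind: str = "hwe"  # "hwe" | "chromosome"
    p_a_range: tuple = (0.70, 0.90)
    causal_p_a_range: tuple = (0.8321, 0.8817)
    causal_idx: tuple = ()
    c: tuple = ()
    alpha: float = 0.0
    n_trait_sets: int = 1
    n_replicates: int = 100
    generations: float = CHROM_GENERATIONS
    fidelity: float = CHROM_FIDELITY
    seed: int = 0

    def __post_init__(self):
        if any(j < 0 or j >= self.n_loci for j in self.causal_idx):
            raise ValueError("causal indices out of range")
        if len(self.c) != len(self.causal_idx):
            raise ValueError("one effect multiplier per causal locus")
        if any(cj < 0 for cj in self.c):
            raise ValueError("effect multipliers must be >= 0")


@dataclass
class RegionLabels:
    """Per-locus labels partitioning an artificial chromosome."""

    labels: np.ndarray  # strings in {LOCUS1, LOCUS2, REG1, REG2, REG3}
    r_threshold: float

    def indices(self, name: str) -> np.ndarray:
        return np.flatnonzero(self.labels == name)


def map_allele_freq(high_risk_allele_counts, I: int, prior_a: float = 1.0,
                    prior_b: float = 1.0):
    """MAP ancestry-proportion estimate under a Beta prior and HWE counts.

    (count + a - 1) / (2I + a + b - 2); the uniform prior a = b = 1 reduces
    to the sample frequency.
    """
    counts = np.asarray(high_risk_allele_counts, dtype=float)
    if np.any(counts < 0) or np.any(counts > 2 * I):
        raise ValueError("counts must lie in [0, 2I]")
    denom = 2 * I + prior_a + prior_b - 2
    if denom <= 0:
        raise ValueError("invalid prior")
    est = (counts + prior_a - 1) / denom
    if np.any(est < 0) or np.any(est > 1):
        raise ValueError("prior puts the MAP estimate outside [0, 1]")
    return est


def _meta_for(p_a, chrom=None, pos_bp=None, cM=None) -> pd.DataFrame:
    J = len(p_a)
    return pd.DataFrame(
        {
            "locus_id": [f"L{j:04d}" for j in range(J)],
            "chrom": chrom if chrom is not None else np.ones(J, dtype=int),
            "pos_bp": pos_bp if pos_bp is not None else np.arange(1, J + 1) * 1_000_000,
            "cM": cM if cM is not None else np.arange(J, dtype=float),
            "p_a": np.asarray(p_a, dtype=float),
        }
    )


def sim_hwe_panel(p_a, I: int, seed=None) -> AncestryPanel:
    """Independent loci: dosages ~ Binomial(2, p_a,j) per subject (HWE)."""
    rng = np.random.default_rng(seed)
    p_a = np.asarray(p_a, dtype=float)
    if np.any((p_a < 0) | (p_a > 1)):
        raise ValueError("p_a must lie in [0, 1]")
    S = rng.binomial(2, p_a[None, :], size=(I, p_a.size)).astype(np.int8)
    return AncestryPanel(dosage=S, meta=_meta_for(p_a))


def sim_correlated_pair(p_a: float, rho: float, I: int, seed=None):
    """Two HWE-marginal dosage columns coupled by a latent Gaussian.

    S = 0 if Z <= C0, S = 2 if Z > C1, else S = 1, with C0 = Phi^-1((1-p_a)^2)
    and C1 = Phi^-1(1 - p_a^2); (Z1, Z2) standard bivariate normal with
    correlation rho.
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    C0 = norm.ppf((1 - p_a) ** 2)
    C1 = norm.ppf(1 - p_a**2)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    Z = rng.multivariate_normal(np.zeros(2), cov, size=I, method="cholesky")
    S = np.ones_like(Z, dtype=np.int8)
    S[Z <= C0] = 0
    S[Z > C1] = 2
    return S[:, 0], S[:, 1]


def sim_chromosome(loci_cM, p_a, g: float, I: int, seed=None, chrom=None,
                   fidelity: float = 1.0) -> AncestryPanel:
    """Markov block ancestry along a genetic map, two haplotypes per subject.

    Per haplotype the ancestry state switches between adjacent loci with
    probability 1 - exp(-g d / 100) for d cM of map distance (independently
    across chromosome boundaries), refreshing to a Bernoulli(p_a) draw at the
    switch.  Each locus then reports the block state with probability
    ``fidelity``, else an independent Bernoulli(p_a,j) draw — the sporadic
    miscall model for estimated local ancestry.  Dosage is the sum of the
    two reported haplotypes, so marginals stay HWE and the inter-locus
    dosage correlation is fidelity^2 * exp(-g d / 100).
    """
    loci_cM = np.asarray(loci_cM, dtype=float)
    p_a = np.asarray(p_a, dtype=float)
    J = loci_cM.size
    if chrom is None:
        chrom = np.ones(J, dtype=int)
    chrom = np.asarray(chrom)
    d = np.diff(loci_cM)
    same = chrom[1:] == chrom[:-1]
    if np.any(d[same] < 0):
        raise ValueError("map positions must be non-decreasing within a chromosome")
    if not 0.0 <= fidelity <= 1.0:
        raise ValueError("fidelity must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    dosage = np.zeros((I, J), dtype=np.int8)
    for _hap in range(2):
        h = (rng.random(I) < p_a[0]).astype(np.int8)
        block = np.empty((I, J), dtype=np.int8)
        block[:, 0] = h
        for j in range(1, J):
            if same[j - 1]:
                keep = rng.random(I) < np.exp(-g * d[j - 1] / 100.0)
            else:
                keep = np.zeros(I, dtype=bool)
            fresh = (rng.random(I) < p_a[j]).astype(np.int8)
            h = np.where(keep, h, fresh)
            block[:, j] = h
        if fidelity < 1.0:
            miscall = rng.random((I, J)) >= fidelity
            noise = (rng.random((I, J)) < p_a[None, :]).astype(np.int8)
            block = np.where(miscall, noise, block)
        dosage += block

    pos_bp = np.round(loci_cM * 1_000_000).astype(np.int64) + 1
    meta = _meta_for(p_a, chrom=chrom, pos_bp=pos_bp, cM=loci_cM)
    return AncestryPanel(dosage=dosage, meta=meta)


def artificial_chromosome_map():
    """Genetic map of the two-piece artificial genome (1 cM/Mb).

    Returns (cM, chrom, causal_idx): 51 equally spaced loci per piece,
    causal locus in the middle (index 25) of each piece.
    """
    cMs, chroms = [], []
    for c, length in enumerate(PIECE_LENGTHS_MB, start=1):
        spacing = length / (LOCI_PER_PIECE - 1)
        cMs.append(np.arange(LOCI_PER_PIECE) * spacing)
        chroms.append(np.full(LOCI_PER_PIECE, c, dtype=int))
    cM = np.concatenate(cMs)
    chrom = np.concatenate(chroms)
    causal = (25, LOCI_PER_PIECE + 25)
    return cM, chrom, causal


def sim_traits(panel: AncestryPanel, design: SimDesign, seed=None):
    """Simulate (TraitVector, covariate E) from a panel under the design.

    Uses uncentered dosages and no intercept, exactly as the generating
    models are written; beta_j = c_j * p_a,j at the causal loci.
    """
    from .glm_core import TraitVector

    rng = np.random.default_rng(seed)
    I = panel.n_subjects
    E = rng.standard_normal(I)
    eta = design.alpha * E
    for j, cj in zip(design.causal_idx, design.c):
        beta_j = cj * float(panel.meta["p_a"].iloc[j])
        eta = eta + beta_j * panel.dosage[:, j].astype(float)
    if design.family == "gaussian":
        y = eta + rng.standard_normal(I)
    elif design.family == "binomial":
        y = (rng.random(I) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
    elif design.family == "poisson":
        y = rng.poisson(np.exp(eta)).astype(float)
    else:
        raise ValueError(f"unknown family {design.family!r}")
    return TraitVector(values=y, family=design.family), E.reshape(-1, 1)


def dichotomize_extremes(y, q: float = 0.2):
    """Label the top q fraction as cases, bottom q as controls; mask the rest.

    Returns (labels, mask): labels is 0/1 where mask is True; ties are broken
    by stable sort order.
    """
    y = np.asarray(y, dtype=float)
    if not 0.0 < q < 0.5:
        raise ValueError("q must lie in (0, 0.5)")
    n = y.size
    k = int(np.floor(q * n))
    if k < 1 or np.ptp(y) == 0:
        raise ValueError("degenerate trait for extreme-sampling")
    order = np.argsort(y, kind="stable")
    labels = np.zeros(n, dtype=float)
    mask = np.zeros(n, dtype=bool)
    mask[order[:k]] = True  # controls (label 0)
    mask[order[-k:]] = True
    labels[order[-k:]] = 1.0
    return labels, mask


def classify_regions(panel: AncestryPanel, causal, r_threshold: float = R_THRESHOLD
                     ) -> RegionLabels:
    """Partition loci by realized dosage correlation with the causal pair.

    REG1: correlation with Locus 1 above threshold; REG2: with Locus 2
    (excluding REG1); REG3: the remainder.
    """
    i1, i2 = causal
    if i1 == i2:
        raise ValueError("causal loci must be distinct")
    S = panel.dosage.astype(float)
    Sc = S - S.mean(axis=0)
    sd = Sc.std(axis=0)
    sd[sd == 0] = np.inf  # constant loci cannot correlate
    r1 = (Sc * Sc[:, [i1]]).mean(axis=0) / (sd * sd[i1])
    r2 = (Sc * Sc[:, [i2]]).mean(axis=0) / (sd * sd[i2])
    labels = np.full(panel.n_loci, "REG3", dtype=object)
    labels[np.abs(r1) > r_threshold] = "REG1"
    labels[(np.abs(r2) > r_threshold) & (labels != "REG1")] = "REG2"
    labels[i1] = "LOCUS1"
    labels[i2] = "LOCUS2"
    return RegionLabels(labels=np.asarray(labels, dtype=object),
                        r_threshold=r_threshold)


# ---------------------------------------------------------------------------
# canned designs
# ---------------------------------------------------------------------------

def null_design(family="gaussian", alpha=0.0, n_loci=1000, n_subjects=1000,
                n_trait_sets=10, n_replicates=100, seed=0) -> SimDesign:
    """Linkage-equilibrium null: no causal locus, HWE panel."""
    return SimDesign(
        family=family, n_subjects=n_subjects, n_loci=n_loci, panel_kind="hwe",
        alpha=alpha, n_trait_sets=n_trait_sets, n_replicates=n_replicates,
        seed=seed,
    )


def single_locus_design(c, family="gaussian", alpha=0.0, n_loci=1000,
                        n_subjects=1000, n_replicates=100, seed=0) -> SimDesign:
    """One causal locus with p_a drawn from the top-quintile range."""
    return SimDesign(
        family=family, n_subjects=n_subjects, n_loci=n_loci, panel_kind="hwe",
        causal_idx=(n_loci // 2,), c=(c,), alpha=alpha,
        n_replicates=n_replicates, seed=seed,
    )


def two_locus_design(family="gaussian", alpha=1.0, n_replicates=100, seed=0,
                     c=None) -> SimDesign:
    """Artificial-chromosome two-locus design (c = 0.7 gaussian / 0.35 binary)."""
    if c is None:
        c = 0.7 if family == "gaussian" else 0.35
    _, _, causal = artificial_chromosome_map()
    return SimDesign(
        family=family, n_subjects=1000, n_loci=2 * LOCI_PER_PIECE,
        panel_kind="chromosome", causal_idx=causal, c=(c, c), alpha=alpha,
        n_replicates=n_replicates, seed=seed,
    )


def _build_panel(design: SimDesign, rng: np.random.Generator) -> AncestryPanel:
    lo, hi = design.p_a_range
    clo, chi = design.causal_p_a_range
    if design.panel_kind == "hwe":
        p_a = rng.uniform(lo, hi, size=design.n_loci)
        for j in design.causal_idx:
            p_a[j] = rng.uniform(clo, chi)
        return sim_hwe_panel(p_a, design.n_subjects, seed=rng)
    if design.panel_kind == "chromosome":
        cM, chrom, _ = artificial_chromosome_map()
        p_a = rng.uniform(lo, hi, size=design.n_loci)
        for j in design.causal_idx:
            p_a[j] = rng.uniform(clo, chi)
        return sim_chromosome(cM, p_a, design.generations, design.n_subjects,
                              seed=rng, chrom=chrom, fidelity=design.fidelity)
    raise ValueError(f"unknown panel kind {design.panel_kind!r}")


def run_experiment(design: SimDesign, methods, cfg=None, n_replicates=None
                   ) -> "ExperimentResult":
    """Replicate the design, run each method, tabulate identification rates.

    Per replicate a fresh panel and trait set(s) are generated from seeds
    spawned deterministically from the design's master seed.  ``methods`` is
    a subset of {"GLEAM1", "GLEAM2", "lasso", "enet"}.  For two-locus
    designs the summary reports, per method: per-locus identification rates
    in REG1/REG2/REG3 and the mutually exclusive Locus1 / Locus2 / Locus1&2
    replicate frequencies.  For null designs it reports per-trait-set type-I
    error rates.
    """
    from .comparators import penalized_scan
    from .two_stage_mapping import ScanConfig, run_gleam

    if cfg is None:
        cfg = ScanConfig(family=design.family)
    cfg = replace(cfg, family=design.family)
    methods = list(methods)
    bad = set(methods) - {"GLEAM1", "GLEAM2", "lasso", "enet"}
    if bad:
        raise ValueError(f"unknown methods {bad}")
    n_rep = design.n_replicates if n_replicates is None else n_replicates

    two_locus = len(design.causal_idx) == 2
    rows = []
    ss = np.random.SeedSequence(design.seed)
    rep_seeds = ss.spawn(n_rep)
    for rep, rep_ss in enumerate(rep_seeds):
        panel_ss, *trait_ss = rep_ss.spawn(design.n_trait_sets + 1)
        rng = np.random.default_rng(panel_ss)
        panel = _build_panel(design, rng)
        regions = (classify_regions(panel, design.causal_idx)
                   if two_locus else None)
        for ts, t_ss in enumerate(trait_ss):
            y, E = sim_traits(panel, design, seed=np.random.default_rng(t_ss))
            for method in methods:
                identified = _run_method(method, panel, y, E, cfg,
                                         seed=rep * 1009 + ts)
                rows.append(_tabulate(method, rep, ts, identified, regions,
                                      design, panel.n_loci))
    table = pd.DataFrame(rows)
    return ExperimentResult(per_replicate=table, design=design,
                            two_locus=two_locus)


def _run_method(method, panel, y, E, cfg, seed):
    from .comparators import penalized_scan
    from .two_stage_mapping import run_gleam

    if method in ("GLEAM1", "GLEAM2"):
        report = run_gleam(panel, y, E, cfg, two_stage=(method == "GLEAM2"))
        return set(report.identified)
    res = penalized_scan(panel, y, E, method=method, family=y.family, seed=seed)
    return set(res.selected)


def _tabulate(method, rep, ts, identified, regions, design, n_loci):
    row = {"method": method, "replicate": rep, "trait_set": ts,
           "n_identified": len(identified)}
    if regions is not None:
        i1, i2 = design.causal_idx
        for name in ("REG1", "REG2", "REG3"):
            idx = regions.indices(name)
            row[f"{name}_hits"] = len(identified & set(idx.tolist()))
            row[f"{name}_size"] = idx.size
        got1, got2 = i1 in identified, i2 in identified
        row["locus1_only"] = got1 and not got2
        row["locus2_only"] = got2 and not got1
        row["locus12"] = got1 and got2
    else:
        n_causal = len(design.causal_idx)
        false = identified - set(design.causal_idx)
        row["type1"] = len(false) / max(n_loci - n_causal, 1)
        if n_causal:
            row["power"] = len(identified & set(design.causal_idx)) / n_causal
    return row


@dataclass
class ExperimentResult:
    """Per-replicate table plus aggregated frequency summaries."""

    per_replicate: pd.DataFrame
    design: SimDesign
    two_locus: bool

    def frequency_table(self) -> pd.DataFrame:
        """Table-style summary for two-locus designs.

        REG columns are per-locus rates (region hits / (region size x
        runs)); Locus columns are mutually exclusive replicate frequencies.
        """
        if not self.two_locus:
            raise ValueError("frequency_table applies to two-locus designs")
        out = []
        for method, grp in self.per_replicate.groupby("method", sort=False):
            row = {"method": method}
            for name in ("REG1", "REG2", "REG3"):
                denom = float((grp[f"{name}_size"]).sum())
                row[name] = grp[f"{name}_hits"].sum() / denom if denom else 0.0
            row["Locus1"] = grp["locus1_only"].mean()
            row["Locus2"] = grp["locus2_only"].mean()
            row["Locus12"] = grp["locus12"].mean()
            out.append(row)
        return pd.DataFrame(out).set_index("method")

    def type1_summary(self) -> pd.DataFrame:
        """Null-design summary: per-method median/quartiles of the per-run
        type-I error rate (each run pools the design's trait sets)."""
        if self.two_locus:
            raise ValueError("type1_summary applies to designs without LD regions")
        grp = (self.per_replicate
               .groupby(["method", "replicate"])["type1"].mean()
               .groupby("method"))
        return grp.agg(median="median", q25=lambda s: s.quantile(0.25),
                       q75=lambda s: s.quantile(0.75), max="max")
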