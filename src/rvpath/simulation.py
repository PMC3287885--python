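"""Synthetic mini-exome generator and the method-evaluation harness.

The generator emulates the structure of a mini-exome case/control
resource: a few hundred to a few thousand genes with a rare-dominated
MAF spectrum, Hardy–Weinberg genotypes, a small subset of causal SNPs
whose log-odds effects drive a dichotomous phenotype, many phenotype
replicates simulated on one fixed genotype matrix, and optionally a
handful of noncausal genes whose columns are near-copies of causal SNPs
(standing in for gametic phase disequilibrium, the mechanism that makes
noncausal genes spuriously associated).

The harness computes, for every (gene set, method, replicate), a
pathway p-value using the tests in :mod:`rvpath.pathway_tests`, then
summarizes empirical type I error / power per set and method, calls the
best method per set, and characterizes when the weighted-sum method is
best via logistic regression on set features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit
from scipy import stats

from rvpath._utils import ValidationError, derived_rng
from rvpath.gene_tests import (
    METHODS,
    _hotelling_batch,
    _ws_rank_sums,
    cmc_design,
    VariantGroup,
    pooled_group,
)
from rvpath.io_formats import (
    MISSING,
    GeneMap,
    GeneSet,
    GenotypeMatrix,
    PhenotypeReplicates,
)
from rvpath.pathway_tests import P_FLOOR, _ks_2sample
from rvpath.set_construction import SetFeatures, TruthModel, set_features

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Generator settings.

    Defaults mirror the dimensions of a public mini-exome benchmark:
    697 individuals, ~3,205 genes, a MAF spectrum with floor 7.17e−4
    dominated by rare variants, 160 causal SNPs in 36 genes, and 200
    phenotype replicates on fixed genotypes.  ``desk_scale`` gives the
    reduced profile used for routine evaluation runs.

    Effect sizes: with ``effect_model='log_maf'`` a causal SNP of minor
    allele frequency f gets log-odds β = effect_scale·|log10 f| (rarer
    variants carry larger effects, the canonical rare-variant
    architecture); ``'fixed'`` assigns ``beta_fixed`` to every causal
    SNP.  ``causal_maf_range`` optionally restricts which variants may
    be causal, e.g. to plant a few strong common-variant effects.
    """

    n_individuals: int = 697
    n_genes: int = 3205
    snps_per_gene_mean: float = 7.6
    maf_floor: float = 7.17e-4
    maf_beta_a: float = 0.2
    maf_beta_b: float = 2.0
    n_causal_genes: int = 36
    n_causal_snps: int = 160
    effect_model: str = "log_maf"
    effect_scale: float = 0.4
    beta_fixed: float = 1.0
    causal_maf_range: tuple[float, float] | None = None
    target_prevalence: float = 0.3
    n_replicates: int = 200
    ld_spurious_genes: int = 0
    ld_fidelity: float = 0.99
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.target_prevalence < 1.0):
            raise ValidationError("target_prevalence must be in (0, 1)")
        if not (0.0 < self.maf_floor < 0.5):
            raise ValidationError("maf_floor must be in (0, 0.5)")
        if self.n_causal_genes > self.n_genes:
            raise ValidationError("more causal genes than genes")
        if self.n_causal_snps < self.n_causal_genes:
            raise ValidationError(
                "need at least one causal SNP per causal gene"
            )
        if not (0.0 <= self.ld_fidelity <= 1.0):
            raise ValidationError("ld_fidelity must be in [0, 1]")
        if self.effect_model not in ("log_maf", "fixed"):
            raise ValidationError(f"unknown effect model {self.effect_model!r}")

    @classmethod
    def desk_scale(cls, **overrides) -> "SimulationConfig":
        """Reduced profile for routine evaluation: 500 individuals,
        300 genes averaging 3 SNPs, 36 causal genes / 72 causal SNPs,
        50 replicates."""
        base = dict(
            n_individuals=500,
            n_genes=300,
            snps_per_gene_mean=3.0,
            n_causal_genes=36,
            n_causal_snps=72,
            n_replicates=50,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "causal_maf_range" in raw and raw["causal_maf_range"] is not None:
            raw["causal_maf_range"] = tuple(raw["causal_maf_range"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        if data["causal_maf_range"] is not None:
            data["causal_maf_range"] = list(data["causal_maf_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass
class EvalParams:
    """Knobs of the evaluation harness."""

    ws_permutations: int = 200
    gsea_permutations: int = 100
    rare_threshold: float = 0.05
    weight_exponent: float = 1.0
    cmc_grouping: str = "gene"
    ks_alternative: str = "greater"


@dataclass
class EvaluationSummary:
    """Per-set, per-method rejection rates, best-method calls, features."""

    pvalues: pd.DataFrame
    rates: pd.DataFrame
    best: pd.DataFrame
    features: pd.DataFrame | None
    n_replicates: int

    def rate(self, set_name: str, method: str, alpha: float) -> float:
        df = self.rates
        row = df[
            (df["set"] == set_name)
            & (df["method"] == method)
            & (np.isclose(df["alpha"], alpha))
        ]
        if row.empty:
            raise KeyError((set_name, method, alpha))
        return float(row["rate"].iloc[0])


# ---------------------------------------------------------------------------
# Genotype generation
# ---------------------------------------------------------------------------


def simulate_genotypes(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, GeneMap, TruthModel]:
    """Draw a mini-exome: HWE genotypes, causal SNP effects, LD copies.

    Per-variant MAFs come from a Beta(a, b) rescaled to
    (maf_floor, 0.5]; dosages are two independent allele draws per
    individual (variants independent).  If ``ld_spurious_genes`` > 0,
    that many noncausal genes have each column replaced by a copy of a
    random causal SNP column with per-allele flip probability
    1 − ld_fidelity, inducing correlation with the disease model.
    """
    rng = derived_rng(config.seed, "genotypes")
    n_genes = config.n_genes
    gene_names = [f"G{i:04d}" for i in range(n_genes)]
    lam = max(config.snps_per_gene_mean - 1.0, 0.0)
    snp_counts = 1 + rng.poisson(lam, size=n_genes)
    m = int(snp_counts.sum())
    variant_ids = [f"V{j:06d}" for j in range(m)]
    variant_gene = np.repeat(gene_names, snp_counts)

    maf = config.maf_floor + (0.5 - config.maf_floor) * rng.beta(
        config.maf_beta_a, config.maf_beta_b, size=m
    )
    dosages = rng.binomial(2, maf, size=(config.n_individuals, m)).astype(
        np.int8
    )

    # --- causal architecture ---------------------------------------------
    if config.causal_maf_range is not None:
        lo, hi = config.causal_maf_range
        snp_ok = (maf >= lo) & (maf <= hi)
        candidate_genes = sorted(set(variant_gene[snp_ok]))
        if len(candidate_genes) < config.n_causal_genes:
            raise ValidationError(
                f"only {len(candidate_genes)} genes contain a SNP in the "
                f"causal MAF range; cannot pick {config.n_causal_genes}"
            )
        causal_genes = sorted(
            str(g)
            for g in rng.choice(
                candidate_genes, size=config.n_causal_genes, replace=False
            )
        )
    else:
        snp_ok = np.ones(m, dtype=bool)
        causal_gene_idx = rng.choice(
            n_genes, size=config.n_causal_genes, replace=False
        )
        causal_genes = sorted(gene_names[i] for i in causal_gene_idx)
    in_causal_gene = np.isin(variant_gene, causal_genes)
    eligible = in_causal_gene & snp_ok
    chosen: list[int] = []
    # one causal SNP per causal gene first, then the remainder at random
    for g in causal_genes:
        cand = np.flatnonzero(eligible & (variant_gene == g))
        if cand.size == 0:
            cand = np.flatnonzero(in_causal_gene & (variant_gene == g))
        chosen.append(int(rng.choice(cand)))
    remaining = np.setdiff1d(np.flatnonzero(eligible), np.asarray(chosen))
    extra = config.n_causal_snps - len(chosen)
    if extra > remaining.size:
        raise ValidationError(
            f"cannot place {config.n_causal_snps} causal SNPs in "
            f"{config.n_causal_genes} causal genes "
            f"({len(chosen) + remaining.size} eligible SNPs)"
        )
    if extra > 0:
        chosen.extend(int(j) for j in rng.choice(remaining, size=extra, replace=False))
    causal_idx = np.sort(np.asarray(chosen))
    if config.effect_model == "log_maf":
        beta = config.effect_scale * np.abs(np.log10(maf[causal_idx]))
    else:
        beta = np.full(causal_idx.size, config.beta_fixed)

    # --- linkage-copy (spurious-association) genes ------------------------
    ld_genes: list[str] = []
    if config.ld_spurious_genes > 0:
        noncausal = [g for g in gene_names if g not in set(causal_genes)]
        if config.ld_spurious_genes > len(noncausal):
            raise ValidationError("more LD genes requested than noncausal genes")
        ld_genes = sorted(
            rng.choice(noncausal, size=config.ld_spurious_genes, replace=False)
        )
        flip_p = 1.0 - config.ld_fidelity
        for g in ld_genes:
            for j in np.flatnonzero(variant_gene == g):
                src = int(rng.choice(causal_idx))
                d = dosages[:, src]
                a1 = (d >= 1).astype(np.int8)
                a2 = (d == 2).astype(np.int8)
                if flip_p > 0:
                    f1 = rng.random(d.size) < flip_p
                    f2 = rng.random(d.size) < flip_p
                    a1 = np.where(f1, 1 - a1, a1)
                    a2 = np.where(f2, 1 - a2, a2)
                dosages[:, j] = a1 + a2

    genotypes = GenotypeMatrix.from_dosages(
        [f"I{i:04d}" for i in range(config.n_individuals)],
        variant_ids,
        dosages,
        variant_gene,
    )
    gene_map = GeneMap(dict(zip(variant_ids, (str(g) for g in variant_gene))))
    truth = TruthModel(
        causal_genes=causal_genes,
        causal_variant_ids=np.asarray(variant_ids, dtype=object)[causal_idx],
        causal_variant_gene=variant_gene[causal_idx].astype(object),
        maf=maf[causal_idx],
        beta=beta,
        ld_genes=list(ld_genes),
    )
    return genotypes, gene_map, truth


def _linear_predictor(
    truth: TruthModel, genotypes: GenotypeMatrix
) -> np.ndarray:
    col = {v: j for j, v in enumerate(genotypes.variant_ids)}
    idx = np.asarray([col[v] for v in truth.causal_variant_ids], dtype=np.intp)
    G = genotypes.dosages[:, idx]
    G = np.where(G == MISSING, 0, G).astype(float)
    return G @ truth.beta


def calibrate_intercept(
    truth: TruthModel,
    genotypes: GenotypeMatrix,
    target_prevalence: float,
) -> float:
    """Intercept β₀ making mean logistic(β₀ + Σβg) equal the target."""
    if not (0.0 < target_prevalence < 1.0):
        raise ValidationError("target_prevalence must be in (0, 1)")
    eta = _linear_predictor(truth, genotypes)

    def gap(b0: float) -> float:
        return float(expit(b0 + eta).mean() - target_prevalence)

    lo, hi = -50.0, 50.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise ValidationError("no intercept in [-50, 50] attains the target")
    return float(brentq(gap, lo, hi, xtol=1e-10))


def simulate_phenotypes(
    truth: TruthModel,
    genotypes: GenotypeMatrix,
    beta0: float,
    n_replicates: int,
    seed: int = 0,
) -> PhenotypeReplicates:
    """Independent Bernoulli(logistic(β₀ + Σβg)) replicates on fixed genotypes."""
    if not np.isfinite(beta0):
        raise ValidationError("intercept must be finite")
    prob = expit(beta0 + _linear_predictor(truth, genotypes))
    n = genotypes.n_individuals
    status = np.empty((n, n_replicates), dtype=np.int8)
    for r in range(n_replicates):
        rng = derived_rng(seed, "phenotype", r)
        col = rng.binomial(1, prob).astype(np.int8)
        if col.sum() in (0, n):
            col = rng.binomial(1, prob).astype(np.int8)
            if col.sum() in (0, n):
                raise ValidationError(
                    f"replicate {r} degenerate twice; prevalence too extreme"
                )
        status[:, r] = col
    phen = PhenotypeReplicates(
        individual_ids=list(genotypes.individual_ids), status=status
    )
    phen.validate()
    return phen


# ---------------------------------------------------------------------------
# Evaluation harness
# ---------------------------------------------------------------------------


def gene_level_results(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeReplicates,
    gene_map: GeneMap,
    params: EvalParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """WS and CMC p-values for every gene × replicate, long-form.

    This is the input the spurious-gene filter consumes: one row per
    (unit_id, method, replicate).  Genes whose CMC design has no
    variation get p = 1.
    """
    params = params or EvalParams()
    phenotypes = phenotypes.aligned_to(genotypes)
    R = phenotypes.n_replicates
    by_gene = gene_map.variant_indices_by_gene(genotypes)
    gene_ids = sorted(by_gene)
    designs: dict[str, np.ndarray | None] = {}
    for g in gene_ids:
        try:
            designs[g] = cmc_design(
                genotypes,
                VariantGroup(label=g, variant_indices=by_gene[g]),
                rare_threshold=params.rare_threshold,
            ).columns
        except ValidationError:
            designs[g] = None
    Y = phenotypes.status.astype(float)
    rows: list[tuple[str, str, int, float]] = []
    for g in gene_ids:
        X = designs[g]
        pvals = _hotelling_batch(X, Y) if X is not None else np.ones(R)
        rows.extend((g, "CMC", r, float(pvals[r])) for r in range(R))
    B = params.ws_permutations
    for r in range(R):
        y = phenotypes.status[:, r].astype(float)
        pool = _permutation_matrix(y, B, derived_rng(seed, "ws_pool", r))
        for g in gene_ids:
            G = genotypes.dosages[:, by_gene[g]]
            x_all, *_ = _ws_rank_sums(
                G, np.concatenate([y[:, None], pool], axis=1)
            )
            p = (1.0 + np.sum(x_all[1:] >= x_all[0] - 1e-12)) / (B + 1.0)
            rows.append((g, "WS", r, float(p)))
    return pd.DataFrame(rows, columns=["unit_id", "method", "replicate", "p_value"])


def _permutation_matrix(
    y: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    out = np.empty((y.size, n_perm))
    for b in range(n_perm):
        out[:, b] = rng.permutation(y)
    return out


def _es_batch(
    scores: np.ndarray,
    gene_order_key: np.ndarray,
    masks: np.ndarray,
    set_sizes: np.ndarray,
    weight_exponent: float,
) -> np.ndarray:
    """Enrichment scores for many profiles × many sets.

    scores: (B, N); gene_order_key: (N,) integer tie-break key
    (position of the gene id in sorted order); masks: (S, N) boolean.
    Returns (B, S).
    """
    B, N = scores.shape
    S = masks.shape[0]
    out = np.empty((B, S))
    miss_step = 1.0 / (N - set_sizes)  # (S,)
    for b in range(B):
        order = np.lexsort((gene_order_key, -scores[b]))
        w = np.abs(scores[b][order]) ** weight_exponent  # (N,)
        hit = masks[:, order]  # (S, N)
        hit_w = np.where(hit, w[None, :], 0.0)
        denom = hit_w.sum(axis=1)
        degenerate = denom <= 0.0
        if degenerate.any():
            hit_w[degenerate] = hit[degenerate] / set_sizes[degenerate, None]
            denom[degenerate] = 1.0
        steps = hit_w / denom[:, None] - (~hit) * miss_step[:, None]
        running = np.cumsum(steps, axis=1)
        absr = np.abs(running)
        near_max = absr >= absr.max(axis=1, keepdims=True) - 1e-12
        idx = near_max.argmax(axis=1)  # earliest position within tolerance
        out[b] = running[np.arange(S), idx]
    return out


def evaluate_methods(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeReplicates,
    gene_map: GeneMap,
    sets: list[GeneSet],
    methods: tuple[str, ...] = METHODS,
    alphas: tuple[float, ...] = (0.05, 0.005),
    params: EvalParams | None = None,
    seed: int = 0,
    truth: TruthModel | None = None,
) -> EvaluationSummary:
    """Pathway p-values for every (set, method, replicate), summarized.

    Gene-level results are computed once per replicate and shared by all
    aggregation methods and sets.  Weighted-sum permutation p-values use
    one pool of phenotype relabelings per replicate — every permuted
    phenotype of that replicate has the same case count, so a single
    Monte Carlo pool serves the observed phenotype, all GSEA outer
    shuffles, and the direct set tests.
    """
    params = params or EvalParams()
    if not sets:
        raise ValidationError("no sets to evaluate")
    bad = [m for m in methods if m not in METHODS]
    if bad:
        raise ValidationError(f"unknown methods: {bad}")
    phenotypes = phenotypes.aligned_to(genotypes)
    R = phenotypes.n_replicates
    n = genotypes.n_individuals

    need_ws_profile = bool({"WS_Fisher", "WS_KS", "WS_GSEA"} & set(methods))
    need_cmc_profile = bool({"CMC_Fisher", "CMC_KS", "CMC_GSEA"} & set(methods))
    need_gsea = bool({"WS_GSEA", "CMC_GSEA"} & set(methods))
    need_ws_direct = "WS" in methods
    need_cmc_direct = "CMC" in methods

    by_gene = gene_map.variant_indices_by_gene(genotypes)
    gene_ids = sorted(by_gene)
    N = len(gene_ids)
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    masks = np.zeros((len(sets), N), dtype=bool)
    for s, gs in enumerate(sets):
        unknown = set(gs.genes) - set(gene_pos)
        if unknown:
            raise ValidationError(
                f"set {gs.name!r} has genes without variants "
                f"(first: {sorted(unknown)[0]!r})"
            )
        masks[s, [gene_pos[g] for g in gs.genes]] = True
    set_sizes = masks.sum(axis=1)
    gene_order_key = np.arange(N)  # gene_ids already sorted

    gene_G = {g: genotypes.dosages[:, by_gene[g]] for g in gene_ids} if (
        need_ws_profile
    ) else {}
    gene_designs: dict[str, np.ndarray | None] = {}
    if need_cmc_profile:
        for g in gene_ids:
            try:
                gene_designs[g] = cmc_design(
                    genotypes,
                    VariantGroup(label=g, variant_indices=by_gene[g]),
                    rare_threshold=params.rare_threshold,
                ).columns
            except ValidationError as exc:
                logger.warning("gene %r: %s; CMC p-value fixed at 1", g, exc)
                gene_designs[g] = None

    pooled = {
        gs.name: pooled_group(genotypes, gene_map, gs.genes, gs.name)
        for gs in sets
    } if (need_ws_direct or need_cmc_direct) else {}

    rows: list[tuple[str, str, int, float]] = []

    # Direct CMC: designs are phenotype-free, so all replicates go in one
    # batched Hotelling call per set.
    if need_cmc_direct:
        Y = phenotypes.status.astype(float)
        for gs in sets:
            try:
                X = cmc_design(
                    genotypes, pooled[gs.name],
                    rare_threshold=params.rare_threshold,
                    grouping=params.cmc_grouping,
                ).columns
                pvals = _hotelling_batch(X, Y)
            except ValidationError as exc:
                logger.warning("set %r CMC: %s; p fixed at 1", gs.name, exc)
                pvals = np.ones(R)
            rows.extend(
                (gs.name, "CMC", r, float(pvals[r])) for r in range(R)
            )

    B_ws = params.ws_permutations
    B_g = params.gsea_permutations
    for r in range(R):
        y = phenotypes.status[:, r].astype(float)
        pool = (
            _permutation_matrix(y, B_ws, derived_rng(seed, "ws_pool", r))
            if (need_ws_profile or need_ws_direct)
            else None
        )
        P_outer = (
            _permutation_matrix(y, B_g, derived_rng(seed, "gsea_outer", r))
            if need_gsea
            else None
        )

        ws_p = np.ones(N)
        ws_p_outer = np.empty((B_g, N)) if need_gsea and need_ws_profile else None
        if need_ws_profile:
            cols = [y[:, None]]
            if ws_p_outer is not None:
                cols.append(P_outer)
            obs_cols = np.concatenate(cols, axis=1)
            for i, g in enumerate(gene_ids):
                x_all, *_ = _ws_rank_sums(
                    gene_G[g], np.concatenate([obs_cols, pool], axis=1)
                )
                x_obs = x_all[: obs_cols.shape[1]]
                x_pool = x_all[obs_cols.shape[1]:]
                exceed = (x_pool[None, :] >= x_obs[:, None] - 1e-12).sum(axis=1)
                p_all = (1.0 + exceed) / (B_ws + 1.0)
                ws_p[i] = p_all[0]
                if ws_p_outer is not None:
                    ws_p_outer[:, i] = p_all[1:]

        cmc_p = np.ones(N)
        cmc_p_outer = np.empty((B_g, N)) if need_gsea and need_cmc_profile else None
        if need_cmc_profile:
            cols = [y[:, None]]
            if cmc_p_outer is not None:
                cols.append(P_outer)
            P_all = np.concatenate(cols, axis=1)
            for i, g in enumerate(gene_ids):
                X = gene_designs[g]
                if X is None:
                    if cmc_p_outer is not None:
                        cmc_p_outer[:, i] = 1.0
                    continue
                p_all = _hotelling_batch(X, P_all)
                cmc_p[i] = p_all[0]
                if cmc_p_outer is not None:
                    cmc_p_outer[:, i] = p_all[1:]

        ws_scores = -np.log(np.clip(ws_p, P_FLOOR, 1.0))
        cmc_scores = -np.log(np.clip(cmc_p, P_FLOOR, 1.0))

        ws_testable = np.ones(N, dtype=bool)
        cmc_testable = (
            np.asarray([gene_designs.get(g) is not None for g in gene_ids])
            if need_cmc_profile
            else np.ones(N, dtype=bool)
        )
        for tag, gene_p, scores, p_outer, testable in (
            ("WS", ws_p, ws_scores, ws_p_outer, ws_testable),
            ("CMC", cmc_p, cmc_scores, cmc_p_outer, cmc_testable),
        ):
            if f"{tag}_Fisher" in methods:
                for s, gs in enumerate(sets):
                    m = masks[s] & testable
                    k = int(m.sum())
                    if k == 0:
                        rows.append((gs.name, f"{tag}_Fisher", r, 1.0))
                        continue
                    x2 = float(-2.0 * np.log(gene_p[m]).sum())
                    p = float(stats.chi2.sf(x2, 2 * k))
                    rows.append(
                        (gs.name, f"{tag}_Fisher", r, max(p, P_FLOOR))
                    )
            if f"{tag}_KS" in methods:
                for s, gs in enumerate(sets):
                    _, p = _ks_2sample(
                        scores[masks[s]], scores[~masks[s]],
                        params.ks_alternative,
                    )
                    rows.append((gs.name, f"{tag}_KS", r, p))
            if f"{tag}_GSEA" in methods:
                prof = np.concatenate(
                    [
                        scores[None, :],
                        -np.log(np.clip(p_outer, P_FLOOR, 1.0)),
                    ],
                    axis=0,
                )
                es = _es_batch(
                    prof, gene_order_key, masks, set_sizes,
                    params.weight_exponent,
                )
                exceed = (es[1:] >= es[0][None, :] - 1e-12).sum(axis=0)
                p_sets = (1.0 + exceed) / (B_g + 1.0)
                rows.extend(
                    (gs.name, f"{tag}_GSEA", r, float(p_sets[s]))
                    for s, gs in enumerate(sets)
                )

        if need_ws_direct:
            for gs in sets:
                G_set = genotypes.dosages[:, pooled[gs.name].variant_indices]
                x_all, *_ = _ws_rank_sums(
                    G_set, np.concatenate([y[:, None], pool], axis=1)
                )
                p = (1.0 + np.sum(x_all[1:] >= x_all[0] - 1e-12)) / (B_ws + 1.0)
                rows.append((gs.name, "WS", r, float(p)))

    pvalues = pd.DataFrame(
        rows, columns=["set", "method", "replicate", "p_value"]
    )

    rate_rows = []
    for (set_name, method), grp in pvalues.groupby(["set", "method"]):
        for alpha in alphas:
            rate_rows.append(
                {
                    "set": set_name,
                    "method": method,
                    "alpha": alpha,
                    "rate": float((grp["p_value"] <= alpha).mean()),
                    "n_replicates": R,
                }
            )
    rates = pd.DataFrame(rate_rows)

    best_rows = []
    counts = (
        pvalues.assign(sig=pvalues["p_value"] <= 0.05)
        .groupby(["set", "method"])["sig"]
        .sum()
    )
    for gs in sets:
        sub = counts.loc[gs.name]
        top = int(sub.max())
        best = sorted(sub[sub == top].index)
        best_rows.append(
            {"set": gs.name, "best_methods": "|".join(best), "best_count": top}
        )
    best = pd.DataFrame(best_rows)

    features = None
    if truth is not None:
        feat_rows = []
        for gs in sets:
            f = set_features(gs, truth, gene_map, genotypes)
            feat_rows.append(
                {"set": gs.name, "category": gs.category.value, **asdict(f)}
            )
        features = pd.DataFrame(feat_rows)

    return EvaluationSummary(
        pvalues=pvalues,
        rates=rates,
        best=best,
        features=features,
        n_replicates=R,
    )


# ---------------------------------------------------------------------------
# Best-method characterization
# ---------------------------------------------------------------------------

FEATURE_COLUMNS = [
    "n_causal_genes",
    "n_causal_snps",
    "n_total_snps",
    "avg_maf_causal_genes",
    "weighted_risk_score",
]


@dataclass
class RegressionReport:
    """Fitted logistic model of 'WS is the best method' on set features."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    converged: bool
    separated: bool
    n_sets: int


def fit_ws_best_logit(
    features: pd.DataFrame, ws_best: np.ndarray
) -> RegressionReport:
    """Maximum-likelihood logistic regression of a binary outcome on the
    five set features; complete separation falls back to a ridge-
    penalized fit flagged in the report."""
    import statsmodels.api as sm

    ws_best = np.asarray(ws_best, dtype=float)
    if len(np.unique(ws_best)) < 2:
        raise ValidationError(
            "outcome is constant across sets; no model to fit"
        )
    X = sm.add_constant(features[FEATURE_COLUMNS].astype(float))
    model = sm.Logit(ws_best, X)
    separated = False
    try:
        fit = model.fit(disp=False, maxiter=200)
        converged = bool(fit.mle_retvals.get("converged", True))
        if not converged or not np.all(np.isfinite(fit.bse)):
            raise np.linalg.LinAlgError
        params, bse, pvals = fit.params, fit.bse, fit.pvalues
    except Exception:  # noqa: BLE001 - separation shows up many ways
        separated = True
        logger.warning(
            "logistic fit did not converge (likely separation); "
            "reporting a ridge-penalized fit"
        )
        fit = model.fit_regularized(alpha=1.0, L1_wt=0.0, disp=False)
        params = fit.params
        bse = pd.Series(np.nan, index=params.index)
        pvals = pd.Series(np.nan, index=params.index)
        converged = False
    return RegressionReport(
        params=params,
        bse=bse,
        pvalues=pvals,
        converged=converged,
        separated=separated,
        n_sets=len(features),
    )


def best_method_regression(summary: EvaluationSummary) -> RegressionReport:
    """Model whether WS (direct) is among a set's best methods.

    Ties count WS as best whenever it sits in the argmax set of
    significant-replicate counts at α = 0.05.
    """
    if summary.features is None:
        raise ValidationError(
            "summary lacks set features; pass truth to evaluate_methods"
        )
    merged = summary.best.merge(summary.features, on="set")
    outcome = merged["best_methods"].str.split("|").apply(lambda ms: "WS" in ms)
    return fit_ws_best_logit(merged, outcome.to_numpy())


# ---------------------------------------------------------------------------
# Power curve
# ---------------------------------------------------------------------------


def plot_power_curve(
    summary: EvaluationSummary, path: str | Path, alpha: float = 0.05
) -> None:
    """Mean rejection rate vs number of causal genes, one line per method."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if summary.features is None:
        raise ValidationError("summary lacks set features; cannot group by C")
    df = summary.rates[np.isclose(summary.rates["alpha"], alpha)].merge(
        summary.features[["set", "n_causal_genes"]], on="set"
    )
    fig, ax = plt.subplots(figsize=(7, 5))
    for method, grp in df.groupby("method"):
        curve = grp.groupby("n_causal_genes")["rate"].mean()
        ax.plot(curve.index, curve.values, marker="o", label=method)
    ax.set_xlabel("causal genes in set")
    ax.set_ylabel(f"power (rejection rate at α = {alpha:g})")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
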