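"""Gene-level rare-variant association tests.

Two burden-style statistics operating on any group of variant columns
(a gene or the pooled SNPs of a pathway):

* the weighted-sum (WS) rank test — each variant is weighted inversely
  by its estimated standard deviation under the unaffected-sample allele
  frequency, individuals are scored by their weighted mutation count,
  and the rank sum of affected individuals is referred to a phenotype
  permutation distribution;
* combined multivariate collapsing (CMC) — rare variants are collapsed
  into per-group presence indicators, common variants kept as dosage
  columns, and the case/control mean vectors compared with Hotelling's
  T² using its asymptotic F distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from rvpath._utils import ValidationError, derived_rng
from rvpath.io_formats import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

#: Methods a TestResult may be tagged with.
METHODS = (
    "WS",
    "CMC",
    "WS_Fisher",
    "CMC_Fisher",
    "WS_GSEA",
    "CMC_GSEA",
    "WS_KS",
    "CMC_KS",
)


@dataclass
class VariantGroup:
    """A labelled group of variant columns in a GenotypeMatrix."""

    label: str
    variant_indices: np.ndarray

    def __post_init__(self) -> None:
        self.variant_indices = np.asarray(self.variant_indices, dtype=np.intp)
        if self.variant_indices.size == 0:
            raise ValidationError(f"variant group {self.label!r} is empty")
        if len(np.unique(self.variant_indices)) != self.variant_indices.size:
            raise ValidationError(
                f"variant group {self.label!r} has duplicate indices"
            )

    def validate_against(self, genotypes: GenotypeMatrix) -> None:
        if (self.variant_indices < 0).any() or (
            self.variant_indices >= genotypes.n_variants
        ).any():
            raise ValidationError(
                f"variant group {self.label!r} has out-of-bounds indices"
            )


@dataclass
class WsComputation:
    """Intermediate quantities of the weighted-sum statistic.

    q  — per-variant minor-allele frequency among unaffected individuals,
         with add-one smoothing: q_i = (m_i^U + 1) / (2 n_i^U + 2);
    w  — per-variant weight sqrt(n_i q_i (1 − q_i)), n_i = individuals
         genotyped at variant i;
    gamma — per-individual genetic score Σ_i g_ij / w_i (missing
         dosages contribute 0);
    rank_sum — sum of midranks of gamma over affected individuals.
    """

    q: np.ndarray
    w: np.ndarray
    gamma: np.ndarray
    rank_sum: float


@dataclass
class CmcDesign:
    """Numeric design for the CMC test: collapse indicators + common dosages."""

    label: str
    columns: np.ndarray
    column_labels: list[str]
    rare_threshold: float
    grouping: str

    @property
    def n_columns(self) -> int:
        return self.columns.shape[1]


@dataclass
class TestResult:
    """Statistic and p-value for one unit (gene or set) on one replicate."""

    unit_id: str
    method: str
    statistic: float
    p_value: float
    replicate: int = 0
    n_permutations: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValidationError(
                f"p-value {self.p_value} for {self.unit_id!r} outside (0, 1]"
            )
        if self.n_permutations is not None and self.p_value < 1.0 / (
            self.n_permutations + 1
        ) - 1e-12:
            raise ValidationError(
                "permutation p-value below the attainable floor "
                f"1/(n_permutations+1) for {self.unit_id!r}"
            )


# ---------------------------------------------------------------------------
# Weighted-sum test
# ---------------------------------------------------------------------------


def _check_phenotype(phenotype: np.ndarray) -> np.ndarray:
    y = np.asarray(phenotype)
    if not np.isin(y, (0, 1)).all():
        raise ValidationError("phenotype must be binary 0/1")
    if y.sum() == 0:
        raise ValidationError("no affected individuals")
    if y.sum() == y.size:
        raise ValidationError(
            "all individuals affected; unaffected-frequency weights undefined"
        )
    return y.astype(np.float64)


def _group_dosages(
    genotypes: GenotypeMatrix, group: VariantGroup
) -> np.ndarray:
    group.validate_against(genotypes)
    return genotypes.dosages[:, group.variant_indices]


def _ws_rank_sums(
    G: np.ndarray, P: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Weighted-sum rank statistics for many phenotype columns at once.

    G: (n, k) dosages with MISSING = −1; P: (n, B) binary phenotypes.
    Returns (x, q, w, gamma) where x[b] is the affected rank sum under
    phenotype column b and q, w, gamma are (k, B)/(n, B) arrays.
    All quantities — including the unaffected-sample frequencies and
    weights — are recomputed per column, as required when P holds
    permuted phenotypes.
    """
    observed = G != MISSING
    Gpos = np.where(observed, G, 0).astype(np.float64)
    U = 1.0 - P  # unaffected indicator
    m_u = Gpos.T @ U  # minor alleles among unaffected, (k, B)
    n_u = observed.T.astype(np.float64) @ U  # genotyped unaffected, (k, B)
    q = (m_u + 1.0) / (2.0 * n_u + 2.0)
    n_tot = observed.sum(axis=0).astype(np.float64)[:, None]  # (k, 1)
    w = np.sqrt(n_tot * q * (1.0 - q))
    gamma = Gpos @ (1.0 / w)  # (n, B)
    ranks = stats.rankdata(gamma, axis=0, method="average")
    x = (ranks * P).sum(axis=0)
    return x, q, w, gamma


def ws_statistic(
    genotypes: GenotypeMatrix,
    phenotype: np.ndarray,
    group: VariantGroup,
) -> WsComputation:
    """Weighted-sum computation for one phenotype vector."""
    y = _check_phenotype(phenotype)
    G = _group_dosages(genotypes, group)
    x, q, w, gamma = _ws_rank_sums(G, y[:, None])
    return WsComputation(
        q=q[:, 0], w=w[:, 0], gamma=gamma[:, 0], rank_sum=float(x[0])
    )


def ws_test(
    genotypes: GenotypeMatrix,
    phenotype: np.ndarray,
    group: VariantGroup,
    n_permutations: int = 1000,
    seed: int = 0,
    replicate: int = 0,
    exhaustive: bool = False,
) -> TestResult:
    """WS test with phenotype-permutation significance.

    Each permutation shuffles the case/control labels and recomputes the
    unaffected frequencies, weights, scores and rank sum from scratch.
    One-sided p = (1 + #{x* ≥ x_obs}) / (n_permutations + 1).

    ``exhaustive=True`` enumerates every distinct case/control
    relabeling instead of sampling (exact test; p = proportion of
    relabelings with x* ≥ x_obs, the identity included).  Only feasible
    for small samples.
    """
    y = _check_phenotype(phenotype)
    G = _group_dosages(genotypes, group)
    if exhaustive:
        from itertools import combinations
        from math import comb

        n, k = y.size, int(y.sum())
        n_distinct = comb(n, k)
        if n_distinct > 200_000:
            raise ValidationError(
                f"{n_distinct} distinct relabelings; exhaustive mode is "
                "for small samples"
            )
        P = np.zeros((n, 1 + n_distinct))
        P[:, 0] = y
        for b, idx in enumerate(combinations(range(n), k)):
            P[list(idx), 1 + b] = 1.0
        x, *_ = _ws_rank_sums(G, P)
        p = np.sum(x[1:] >= x[0] - 1e-12) / n_distinct
        return TestResult(
            unit_id=group.label,
            method="WS",
            statistic=float(x[0]),
            p_value=float(p),
            replicate=replicate,
            n_permutations=n_distinct,
        )
    if n_permutations < 1:
        raise ValidationError("n_permutations must be ≥ 1")
    rng = derived_rng(seed, "ws", group.label, replicate)
    P = np.empty((y.size, 1 + n_permutations))
    P[:, 0] = y
    for b in range(n_permutations):
        P[:, 1 + b] = rng.permutation(y)
    x, *_ = _ws_rank_sums(G, P)
    x_obs = x[0]
    p = (1.0 + np.sum(x[1:] >= x_obs - 1e-12)) / (n_permutations + 1.0)
    return TestResult(
        unit_id=group.label,
        method="WS",
        statistic=float(x_obs),
        p_value=float(p),
        replicate=replicate,
        n_permutations=n_permutations,
    )


def _ws_pooled_pvalues(
    G: np.ndarray,
    pheno_cols: np.ndarray,
    pool_cols: np.ndarray,
) -> np.ndarray:
    """Permutation p-values for several phenotype columns via a shared pool.

    All columns of ``pheno_cols`` must have the same case count as the
    relabelings in ``pool_cols``; the permutation null distribution of
    the rank sum is then identical for every column, so one Monte Carlo
    pool of statistics serves them all.
    """
    B = pool_cols.shape[1]
    x_all, *_ = _ws_rank_sums(G, np.concatenate([pheno_cols, pool_cols], axis=1))
    x_obs = x_all[: pheno_cols.shape[1]]
    x_pool = x_all[pheno_cols.shape[1]:]
    exceed = (x_pool[None, :] >= x_obs[:, None] - 1e-12).sum(axis=1)
    return (1.0 + exceed) / (B + 1.0)


# ---------------------------------------------------------------------------
# CMC design + Hotelling's T²
# ---------------------------------------------------------------------------


def cmc_design(
    genotypes: GenotypeMatrix,
    group: VariantGroup,
    rare_threshold: float = 0.05,
    grouping: str = "gene",
) -> CmcDesign:
    """Build the CMC design matrix for a variant group.

    Variants with MAF < ``rare_threshold`` are collapsed into a binary
    any-rare-minor-allele indicator per collapsing unit (per gene, or a
    single unit for the whole group when ``grouping='set'``); common
    variants keep their dosage columns.  Constant columns carry no
    information and are dropped with a warning.
    """
    if not (0.0 < rare_threshold <= 0.5):
        raise ValidationError("rare_threshold must be in (0, 0.5]")
    if grouping not in ("gene", "set"):
        raise ValidationError(f"unknown grouping {grouping!r}")
    G = _group_dosages(genotypes, group)
    maf = np.asarray(genotypes.variant_maf)[group.variant_indices]
    genes = np.asarray(genotypes.variant_gene)[group.variant_indices]
    rare = maf < rare_threshold
    carrier = np.where(G != MISSING, G, 0) > 0

    columns: list[np.ndarray] = []
    labels: list[str] = []
    if rare.any():
        if grouping == "set":
            units = {group.label: np.flatnonzero(rare)}
        else:
            units = {}
            for j in np.flatnonzero(rare):
                units.setdefault(str(genes[j]), []).append(j)
            units = {g: np.asarray(idx) for g, idx in units.items()}
        for unit, idx in sorted(units.items()):
            columns.append(carrier[:, idx].any(axis=1).astype(np.float64))
            labels.append(f"collapse:{unit}")
    for j in np.flatnonzero(~rare):
        columns.append(np.where(G[:, j] != MISSING, G[:, j], 0).astype(np.float64))
        labels.append(f"dosage:{genotypes.variant_ids[group.variant_indices[j]]}")

    X = np.column_stack(columns)
    keep = X.std(axis=0) > 0
    if not keep.all():
        dropped = [l for l, k in zip(labels, keep) if not k]
        logger.warning(
            "CMC design for %r: dropping %d constant column(s): %s",
            group.label, len(dropped), ", ".join(dropped),
        )
    if not keep.any():
        raise ValidationError(
            f"CMC design for {group.label!r} has no non-constant columns"
        )
    return CmcDesign(
        label=group.label,
        columns=X[:, keep],
        column_labels=[l for l, k in zip(labels, keep) if k],
        rare_threshold=rare_threshold,
        grouping=grouping,
    )


def hotelling_t2(
    design: CmcDesign,
    phenotype: np.ndarray,
    replicate: int = 0,
) -> TestResult:
    """Two-sample Hotelling's T² on the design columns.

    T² = (n₁n₂/(n₁+n₂)) d' S_pooled⁻¹ d is converted to
    F = T² (n₁+n₂−p−1) / (p (n₁+n₂−2)) and referred to F(p, n₁+n₂−p−1).
    A singular pooled covariance falls back to the pseudo-inverse with
    degrees of freedom based on the matrix rank.
    """
    y = _check_phenotype(phenotype)
    X = design.columns
    n, p = X.shape
    n1 = int(y.sum())
    n2 = n - n1
    if n1 < 2 or n2 < 2:
        raise ValidationError("Hotelling's T² needs ≥2 cases and ≥2 controls")
    if n1 + n2 - 2 <= p:
        raise ValidationError(
            f"too few individuals ({n}) for {p} design columns"
        )
    cases = X[y == 1]
    controls = X[y == 0]
    d = cases.mean(axis=0) - controls.mean(axis=0)
    S = (
        (n1 - 1) * np.cov(cases, rowvar=False).reshape(p, p)
        + (n2 - 1) * np.cov(controls, rowvar=False).reshape(p, p)
    ) / (n1 + n2 - 2)
    rank = p
    try:
        sol = np.linalg.solve(S, d)
        if not np.all(np.isfinite(sol)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        rank = int(np.linalg.matrix_rank(S))
        if rank == 0:
            raise ValidationError(
                f"pooled covariance for {design.label!r} is zero"
            ) from None
        logger.warning(
            "singular pooled covariance for %r; using pseudo-inverse "
            "with rank %d", design.label, rank,
        )
        sol = np.linalg.pinv(S) @ d
    t2 = (n1 * n2 / (n1 + n2)) * float(d @ sol)
    t2 = max(t2, 0.0)
    df2 = n1 + n2 - rank - 1
    F = t2 * df2 / (rank * (n1 + n2 - 2))
    p_value = float(stats.f.sf(F, rank, df2))
    return TestResult(
        unit_id=design.label,
        method="CMC",
        statistic=t2,
        p_value=max(min(p_value, 1.0), 1e-300),
        replicate=replicate,
    )


def _hotelling_batch(X: np.ndarray, P: np.ndarray) -> np.ndarray:
    """Hotelling p-values for many phenotype columns over one fixed design.

    X: (n, p) design; P: (n, B) binary phenotypes.  Vectorizes the
    per-group scatter matrices with einsum and batch-solves the p×p
    systems; any singular column falls back to the scalar path.
    """
    n, p = X.shape
    B = P.shape[1]
    n1 = P.sum(axis=0)
    n2 = n - n1
    Sx = X.T @ X  # (p, p)
    colsum = X.sum(axis=0)  # (p,)
    sum1 = X.T @ P  # (p, B)
    mean1 = sum1 / n1
    mean2 = (colsum[:, None] - sum1) / n2
    C1 = np.einsum("np,nb,nq->bpq", X, P, X, optimize=True)  # case scatter raw
    scat1 = C1 - n1[:, None, None] * np.einsum("pb,qb->bpq", mean1, mean1)
    scat2 = (Sx[None] - C1) - n2[:, None, None] * np.einsum(
        "pb,qb->bpq", mean2, mean2
    )
    S = (scat1 + scat2) / (n - 2)
    d = (mean1 - mean2).T  # (B, p)
    out = np.empty(B)
    try:
        sol = np.linalg.solve(S, d[..., None])[..., 0]  # (B, p)
        ok = np.all(np.isfinite(sol), axis=1)
    except np.linalg.LinAlgError:
        sol = np.full_like(d, np.nan)
        ok = np.zeros(B, dtype=bool)
    t2 = (n1 * n2 / n) * np.einsum("bp,bp->b", d, sol)
    df2 = n1 + n2 - p - 1
    F = np.clip(t2, 0, None) * df2 / (p * (n - 2))
    out[:] = stats.f.sf(F, p, df2)
    for b in np.flatnonzero(~ok):
        rank = int(np.linalg.matrix_rank(S[b]))
        if rank == 0:
            out[b] = 1.0
            continue
        sol_b = np.linalg.pinv(S[b]) @ d[b]
        t2_b = max((n1[b] * n2[b] / n) * float(d[b] @ sol_b), 0.0)
        df2_b = n1[b] + n2[b] - rank - 1
        out[b] = stats.f.sf(t2_b * df2_b / (rank * (n - 2)), rank, df2_b)
    return np.clip(out, 1e-300, 1.0)


def cmc_test(
    genotypes: GenotypeMatrix,
    phenotype: np.ndarray,
    group: VariantGroup,
    rare_threshold: float = 0.05,
    grouping: str = "gene",
    replicate: int = 0,
) -> TestResult:
    """CMC test: collapse per ``grouping``, then Hotelling's T²."""
    design = cmc_design(genotypes, group, rare_threshold, grouping)
    result = hotelling_t2(design, phenotype, replicate=replicate)
    result.unit_id = group.label
    return result


def gene_groups(
    genotypes: GenotypeMatrix, gene_map
) -> dict[str, VariantGroup]:
    """One VariantGroup per gene, keyed by gene symbol."""
    return {
        g: VariantGroup(label=g, variant_indices=idx)
        for g, idx in gene_map.variant_indices_by_gene(genotypes).items()
    }


def pooled_group(
    genotypes: GenotypeMatrix,
    gene_map,
    genes: Sequence[str],
    label: str,
) -> VariantGroup:
    """Pool every SNP of the named genes into one VariantGroup."""
    by_gene = gene_map.variant_indices_by_gene(genotypes)
    idx: list[np.ndarray] = []
    for g in genes:
        if g in by_gene:
            idx.append(by_gene[g])
    if not idx:
        raise ValidationError(f"no variants found for set {label!r}")
    return VariantGroup(label=label, variant_indices=np.concatenate(idx))
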