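"""Pathway-level significance.

Either the gene-level rare-variant p-values are aggregated over a set
(Fisher's combined probability, two-sample KS on −log p, or the
weighted-KS GSEA running sum with phenotype-permutation significance),
or the WS/CMC statistics are applied directly to the pooled SNPs of the
set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from rvpath._utils import ValidationError, derived_rng
from rvpath.gene_tests import (
    TestResult,
    cmc_test,
    gene_groups,
    pooled_group,
    ws_test,
)
from rvpath.io_formats import GeneMap, GeneSet, GenotypeMatrix

logger = logging.getLogger(__name__)

#: Floor applied to asymptotic p-values before taking −log.
P_FLOOR = 1e-300


@dataclass
class GeneScoreProfile:
    """Per-gene scores −log(p) from one rare-variant method, one replicate.

    ``testable`` marks genes whose test produced a defined p-value;
    genes without testable variation keep score 0 and are excluded from
    Fisher combination (a hard p = 1 is not a draw from the null and
    would deflate the chi-square statistic).
    """

    gene_ids: list[str]
    scores: np.ndarray
    method: str
    testable: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.gene_ids) != self.scores.size:
            raise ValidationError("one score per gene required")
        if len(self.gene_ids) < 2:
            raise ValidationError("a profile needs at least 2 genes")
        if not np.all(np.isfinite(self.scores)) or np.any(self.scores < 0):
            raise ValidationError("scores must be finite and ≥ 0")
        if self.testable is None:
            self.testable = np.ones(self.scores.size, dtype=bool)
        else:
            self.testable = np.asarray(self.testable, dtype=bool)
            if self.testable.size != self.scores.size:
                raise ValidationError("one testable flag per gene required")


@dataclass
class EnrichmentScore:
    """Signed maximal deviation of the GSEA running sum."""

    es: float
    weight_exponent: float

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-12 <= self.es <= 1.0 + 1e-12):
            raise ValidationError(f"enrichment score {self.es} outside [-1, 1]")
        self.es = float(np.clip(self.es, -1.0, 1.0))


# ---------------------------------------------------------------------------
# Gene p-value profile
# ---------------------------------------------------------------------------


def gene_pvalue_profile(
    genotypes: GenotypeMatrix,
    phenotype: np.ndarray,
    gene_map: GeneMap,
    method: str = "WS",
    rare_threshold: float = 0.05,
    n_permutations: int = 1000,
    seed: int = 0,
    replicate: int = 0,
) -> GeneScoreProfile:
    """Run the chosen rare-variant test on every gene; return −log p.

    Genes whose test fails (e.g. no variation in the CMC design) score 0
    with a logged warning, so a single degenerate gene cannot abort a
    whole profile.
    """
    if method not in ("WS", "CMC"):
        raise ValidationError(f"unknown gene-level method {method!r}")
    groups = gene_groups(genotypes, gene_map)
    gene_ids = sorted(groups)
    scores = np.zeros(len(gene_ids))
    testable = np.ones(len(gene_ids), dtype=bool)
    for i, g in enumerate(gene_ids):
        try:
            if method == "WS":
                res = ws_test(
                    genotypes, phenotype, groups[g],
                    n_permutations=n_permutations, seed=seed,
                    replicate=replicate,
                )
            else:
                res = cmc_test(
                    genotypes, phenotype, groups[g],
                    rare_threshold=rare_threshold, replicate=replicate,
                )
            scores[i] = -np.log(max(res.p_value, P_FLOOR))
        except ValidationError as exc:
            logger.warning("gene %r: %s; score set to 0", g, exc)
            testable[i] = False
    return GeneScoreProfile(
        gene_ids=gene_ids, scores=scores, method=method, testable=testable
    )


# ---------------------------------------------------------------------------
# Fisher's combined probability
# ---------------------------------------------------------------------------


def fisher_combined(
    p_values: Sequence[float],
    unit_id: str = "set",
    replicate: int = 0,
    method: str = "WS_Fisher",
) -> TestResult:
    """Fisher's method: X² = −2 Σ ln pᵢ ~ χ²(2k) under the null."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValidationError("no p-values to combine")
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValidationError("p-values for Fisher's method must be in (0, 1]")
    x2 = float(-2.0 * np.log(p).sum())
    combined = float(stats.chi2.sf(x2, 2 * p.size))
    return TestResult(
        unit_id=unit_id,
        method=method,
        statistic=x2,
        p_value=max(min(combined, 1.0), P_FLOOR),
        replicate=replicate,
    )


def fisher_set_test(
    profile: GeneScoreProfile,
    gene_set: GeneSet,
    replicate: int = 0,
) -> TestResult:
    """Fisher's method over a set's gene p-values from a profile.

    Untestable genes carry no information and are excluded (with a
    matching reduction in degrees of freedom); a set with no testable
    gene gets p = 1.
    """
    mask = _in_set_mask(profile, gene_set) & profile.testable
    if not mask.any():
        logger.warning(
            "set %r has no testable genes; Fisher p fixed at 1", gene_set.name
        )
        return TestResult(
            unit_id=gene_set.name,
            method=f"{profile.method}_Fisher",
            statistic=0.0,
            p_value=1.0,
            replicate=replicate,
        )
    result = fisher_combined(
        np.exp(-profile.scores[mask]),
        unit_id=gene_set.name,
        replicate=replicate,
        method=f"{profile.method}_Fisher",
    )
    return result


# ---------------------------------------------------------------------------
# Two-sample KS on the score distributions
# ---------------------------------------------------------------------------


def _in_set_mask(profile: GeneScoreProfile, gene_set: GeneSet) -> np.ndarray:
    members = set(gene_set.genes)
    unknown = members - set(profile.gene_ids)
    if unknown:
        raise ValidationError(
            f"set {gene_set.name!r} has genes absent from the profile "
            f"(first: {sorted(unknown)[0]!r})"
        )
    return np.asarray([g in members for g in profile.gene_ids])


def _ks_2sample(
    x: np.ndarray, y: np.ndarray, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Two-sample KS statistic and asymptotic p-value.

    The two-sided p refers sqrt-free D to the finite-n Kolmogorov
    distribution at the effective sample size n₁n₂/(n₁+n₂); one-sided
    alternatives use the exponential tail bound with Hodges' correction.
    """
    n1, n2 = x.size, y.size
    grid = np.sort(np.concatenate([x, y]))
    cdf1 = np.searchsorted(np.sort(x), grid, side="right") / n1
    cdf2 = np.searchsorted(np.sort(y), grid, side="right") / n2
    n_eff = n1 * n2 / (n1 + n2)
    if alternative == "two-sided":
        d = float(np.max(np.abs(cdf1 - cdf2)))
        p = float(stats.kstwo.sf(d, int(round(n_eff))))
    elif alternative in ("greater", "less"):
        # 'greater': in-set scores stochastically larger, i.e. cdf1 below cdf2
        diff = cdf2 - cdf1 if alternative == "greater" else cdf1 - cdf2
        d = float(np.max(diff))
        m, n = max(n1, n2), min(n1, n2)
        z = np.sqrt(n_eff) * d
        expt = -2 * z**2 - 2 * z * (m + 2 * n) / np.sqrt(m * n * (m + n)) / 3.0
        p = float(np.exp(expt))
    else:
        raise ValidationError(f"unknown alternative {alternative!r}")
    return d, max(min(p, 1.0), P_FLOOR)


def ks_set_test(
    profile: GeneScoreProfile,
    gene_set: GeneSet,
    alternative: str = "greater",
    replicate: int = 0,
) -> TestResult:
    """KS test of in-set vs out-of-set −log p distributions.

    The default alternative 'greater' tests enrichment (in-set scores
    stochastically larger); 'two-sided' also rejects sets depleted
    relative to the background, which is rarely the question a pathway
    screen asks.
    """
    mask = _in_set_mask(profile, gene_set)
    if mask.all():
        raise ValidationError(
            f"set {gene_set.name!r} covers every gene; no complement to test"
        )
    d, p = _ks_2sample(
        profile.scores[mask], profile.scores[~mask], alternative
    )
    return TestResult(
        unit_id=gene_set.name,
        method=f"{profile.method}_KS",
        statistic=d,
        p_value=p,
        replicate=replicate,
    )


# ---------------------------------------------------------------------------
# GSEA (weighted KS running sum)
# ---------------------------------------------------------------------------


def _es_from_ordered(
    hit: np.ndarray, weighted: np.ndarray, label: str = "set"
) -> float:
    """Signed maximal running-sum deviation over an ordered gene list."""
    n = hit.size
    n_hit = int(hit.sum())
    hit_weight = np.where(hit, weighted, 0.0)
    denom = hit_weight.sum()
    if denom <= 0.0:
        logger.warning(
            "GSEA for %r: all in-set weighted scores are 0; "
            "hits weighted uniformly", label,
        )
        hit_weight = hit / n_hit
        denom = 1.0
    steps = hit_weight / denom - (~hit) / (n - n_hit)
    running = np.cumsum(steps)
    # earliest position within fp tolerance of the max |deviation|
    absr = np.abs(running)
    idx = int(np.flatnonzero(absr >= absr.max() - 1e-12)[0])
    return float(running[idx])


def gsea_enrichment_score(
    profile: GeneScoreProfile,
    gene_set: GeneSet,
    weight_exponent: float = 1.0,
) -> EnrichmentScore:
    """Weighted-KS enrichment score of a set in a ranked gene list.

    Genes are ordered by score descending (ties broken by gene id);
    walking the list, in-set genes add score^weight_exponent normalised
    by the in-set total, out-of-set genes subtract 1/(N − |set|).  The
    ES is the running-sum value of maximal absolute deviation.
    weight_exponent = 0 recovers the classic unweighted KS running
    statistic on ranks.
    """
    if weight_exponent < 0:
        raise ValidationError("weight_exponent must be ≥ 0")
    mask = _in_set_mask(profile, gene_set)
    if mask.all():
        raise ValidationError(
            f"set {gene_set.name!r} covers every gene; ES undefined"
        )
    order = np.lexsort((np.asarray(profile.gene_ids), -profile.scores))
    hit = mask[order]
    weighted = np.abs(profile.scores[order]) ** weight_exponent
    es = _es_from_ordered(hit, weighted, gene_set.name)
    return EnrichmentScore(es=es, weight_exponent=weight_exponent)


def gsea_test(
    genotypes: GenotypeMatrix,
    phenotype: np.ndarray,
    gene_map: GeneMap,
    gene_set: GeneSet,
    method: str = "WS",
    n_permutations: int = 100,
    inner_permutations: int = 100,
    weight_exponent: float = 1.0,
    rare_threshold: float = 0.05,
    seed: int = 0,
    replicate: int = 0,
) -> TestResult:
    """GSEA with phenotype-permutation significance.

    Each permutation shuffles the phenotype, recomputes the entire
    gene p-value profile, and recomputes the ES; one-sided
    p = (1 + #{ES* ≥ ES_obs}) / (n_permutations + 1).  Because every
    outer permutation prices a full profile, the inner WS permutation
    count is configurable (and coarser than a standalone gene test).
    """
    if n_permutations < 1:
        raise ValidationError("n_permutations must be ≥ 1")
    if method == "WS" and inner_permutations < 100:
        logger.warning(
            "inner_permutations=%d gives WS p-value granularity %.3g",
            inner_permutations, 1.0 / (inner_permutations + 1),
        )

    def profile_for(y: np.ndarray, tag: int) -> GeneScoreProfile:
        return gene_pvalue_profile(
            genotypes, y, gene_map, method=method,
            rare_threshold=rare_threshold,
            n_permutations=inner_permutations,
            seed=seed, replicate=tag,
        )

    es_obs = gsea_enrichment_score(
        profile_for(np.asarray(phenotype), replicate), gene_set,
        weight_exponent,
    ).es
    rng = derived_rng(seed, "gsea", gene_set.name, replicate)
    exceed = 0
    for b in range(n_permutations):
        y_perm = rng.permutation(np.asarray(phenotype))
        es_b = gsea_enrichment_score(
            profile_for(y_perm, replicate), gene_set, weight_exponent
        ).es
        if es_b >= es_obs - 1e-12:
            exceed += 1
    p = (1.0 + exceed) / (n_permutations + 1.0)
    return TestResult(
        unit_id=gene_set.name,
        method=f"{method}_GSEA",
        statistic=es_obs,
        p_value=p,
        replicate=replicate,
        n_permutations=n_permutations,
    )


# ---------------------------------------------------------------------------
# Direct application of WS / CMC to the pooled set
# ---------------------------------------------------------------------------


def direct_set_test(
    genotypes: GenotypeMatrix,
    phenotype: np.ndarray,
    gene_set: GeneSet,
    gene_map: GeneMap,
    method: str = "WS",
    rare_threshold: float = 0.05,
    n_permutations: int = 1000,
    grouping: str = "gene",
    seed: int = 0,
    replicate: int = 0,
) -> TestResult:
    """WS or CMC applied to every SNP of every gene in the set.

    For CMC the default ``grouping='gene'`` collapses rare variants into
    one indicator per gene (plus common-variant dosage columns);
    ``grouping='set'`` collapses the whole set into a single indicator.
    """
    group = pooled_group(genotypes, gene_map, gene_set.genes, gene_set.name)
    if method == "WS":
        return ws_test(
            genotypes, phenotype, group,
            n_permutations=n_permutations, seed=seed, replicate=replicate,
        )
    if method == "CMC":
        return cmc_test(
            genotypes, phenotype, group,
            rare_threshold=rare_threshold, grouping=grouping,
            replicate=replicate,
        )
    raise ValidationError(f"unknown direct method {method!r}")
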