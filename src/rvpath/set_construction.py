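"""Evaluation gene sets, the spurious-gene filter, and set features.

Evaluation sets of fixed size (default 25 genes) come in four
categories: causal mixtures with C causal genes for several values of
C, all-noncausal (null) sets, null sets restricted to genes without
spurious association, and the causal mixtures with their noncausal
members redrawn from the nonspurious pool.  A noncausal gene is called
spurious when it is jointly significant (both WS and CMC p < α) in more
than a threshold number of phenotype replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from rvpath._utils import ValidationError, derived_rng
from rvpath.io_formats import GeneMap, GeneSet, GenotypeMatrix, SetCategory


@dataclass
class TruthModel:
    """Ground truth of the disease model: causal genes/SNPs and effects.

    ``beta`` is the per-SNP effect on the log-odds scale; ``maf`` the
    minor allele frequency used to assign it.  ``ld_genes`` records
    noncausal genes whose columns were copied from causal SNPs by the
    generator (empty for real data) so spurious-detection performance
    can be scored.
    """

    causal_genes: list[str]
    causal_variant_ids: np.ndarray
    causal_variant_gene: np.ndarray
    maf: np.ndarray
    beta: np.ndarray
    ld_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.causal_variant_ids = np.asarray(self.causal_variant_ids, dtype=object)
        self.causal_variant_gene = np.asarray(self.causal_variant_gene, dtype=object)
        self.maf = np.asarray(self.maf, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        if not np.all(np.isfinite(self.beta)):
            raise ValidationError("causal effect sizes must be finite")
        outside = set(self.causal_variant_gene) - set(self.causal_genes)
        if outside:
            raise ValidationError(
                f"causal SNP in non-causal gene {sorted(outside)[0]!r}"
            )

    @property
    def n_causal_snps(self) -> int:
        return self.causal_variant_ids.size

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "variant_id": self.causal_variant_ids,
                "gene": self.causal_variant_gene,
                "maf": self.maf,
                "beta": self.beta,
            }
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TruthModel":
        df = pd.read_csv(path, sep="\t")
        required = {"variant_id", "gene", "maf", "beta"}
        if not required <= set(df.columns):
            raise ValidationError(
                f"{path}: truth TSV needs columns {sorted(required)}"
            )
        return cls(
            causal_genes=sorted(df["gene"].unique()),
            causal_variant_ids=df["variant_id"].to_numpy(),
            causal_variant_gene=df["gene"].to_numpy(),
            maf=df["maf"].to_numpy(),
            beta=df["beta"].to_numpy(),
        )


@dataclass
class SetFeatures:
    """The five per-set explanatory features.

    avg_maf_causal_genes sums the causal-SNP MAFs within each causal
    gene first, then averages over the set's causal genes; the weighted
    risk score is Σ MAF·β over the set's causal SNPs.
    """

    n_causal_genes: int
    n_causal_snps: int
    n_total_snps: int
    avg_maf_causal_genes: float
    weighted_risk_score: float


def detect_spurious(
    results: pd.DataFrame,
    truth: TruthModel,
    alpha: float = 0.05,
    count_threshold: int = 15,
    n_replicates: int = 200,
    mode: str = "joint",
) -> list[str]:
    """Noncausal genes repeatedly significant across phenotype replicates.

    ``results`` holds one row per (unit_id, method, replicate) with a
    p_value, covering every gene × replicate for both WS and CMC.  In
    ``joint`` mode a replicate counts when BOTH methods give p < alpha;
    a noncausal gene is spurious when that count strictly exceeds
    ``count_threshold``.  ``marginal`` mode instead requires each
    method's own count to exceed the threshold.
    """
    if mode not in ("joint", "marginal"):
        raise ValidationError(f"unknown spurious mode {mode!r}")
    required = {"unit_id", "method", "replicate", "p_value"}
    if not required <= set(results.columns):
        raise ValidationError(f"results need columns {sorted(required)}")
    df = results[results["method"].isin(["WS", "CMC"])]
    counts = df.groupby(["unit_id", "method"])["replicate"].nunique()
    genes = sorted(df["unit_id"].unique())
    for g in genes:
        for m in ("WS", "CMC"):
            if counts.get((g, m), 0) != n_replicates:
                raise ValidationError(
                    f"gene {g!r} is missing {m} results for some replicates"
                )
    wide = df.pivot_table(
        index=["unit_id", "replicate"], columns="method", values="p_value"
    )
    causal = set(truth.causal_genes)
    spurious: list[str] = []
    for g in genes:
        if g in causal:
            continue
        sub = wide.loc[g]
        if mode == "joint":
            count = int(((sub["WS"] < alpha) & (sub["CMC"] < alpha)).sum())
            hit = count > count_threshold
        else:
            hit = (
                int((sub["WS"] < alpha).sum()) > count_threshold
                and int((sub["CMC"] < alpha).sum()) > count_threshold
            )
        if hit:
            spurious.append(g)
    return spurious


def build_sets(
    truth: TruthModel,
    all_genes: list[str],
    nonspurious_genes: list[str],
    set_size: int = 25,
    causal_counts: tuple[int, ...] = (5, 10, 15, 20, 25),
    sets_per_count: int = 100,
    n_null_sets: int = 500,
    seed: int = 0,
) -> list[GeneSet]:
    """Construct the four categories of evaluation sets.

    1. ``causal_mix`` — for each C in causal_counts, sets_per_count sets
       of C causal + (set_size − C) noncausal genes;
    2. ``null`` — n_null_sets all-noncausal sets;
    3. ``null_nonspurious`` — n_null_sets sets from noncausal genes that
       are also nonspurious;
    4. ``causal_mix_nonspurious`` — the category-1 sets with their
       noncausal members redrawn from the nonspurious pool (the causal
       draws are reused, not redrawn).

    Sampling is without replacement within a set; genes may recur
    across sets.  Deterministic given the seed.
    """
    causal = [g for g in all_genes if g in set(truth.causal_genes)]
    noncausal = [g for g in all_genes if g not in set(truth.causal_genes)]
    ns_noncausal = [
        g for g in nonspurious_genes if g not in set(truth.causal_genes)
    ]
    if causal_counts and max(causal_counts) > len(causal):
        raise ValidationError(
            f"only {len(causal)} causal genes available; "
            f"cannot draw C = {max(causal_counts)}"
        )
    if causal_counts and set_size - min(causal_counts) > len(noncausal):
        raise ValidationError("noncausal gene pool too small")
    if n_null_sets and set_size > len(noncausal):
        raise ValidationError("noncausal gene pool smaller than set size")
    if n_null_sets and set_size > len(ns_noncausal):
        raise ValidationError("nonspurious noncausal gene pool too small")
    if causal_counts and set_size - min(causal_counts) > len(ns_noncausal):
        raise ValidationError("nonspurious noncausal gene pool too small")

    rng = derived_rng(seed, "build_sets")
    sets: list[GeneSet] = []
    cat1_causal: list[tuple[int, list[str]]] = []
    for c in causal_counts:
        for i in range(sets_per_count):
            chosen_causal = list(rng.choice(causal, size=c, replace=False))
            chosen_non = list(
                rng.choice(noncausal, size=set_size - c, replace=False)
            )
            cat1_causal.append((c, chosen_causal))
            sets.append(
                GeneSet(
                    name=f"causal_mix_C{c}_{i:03d}",
                    genes=chosen_causal + chosen_non,
                    category=SetCategory.causal_mix,
                    description=f"category=causal_mix C={c}",
                )
            )
    for i in range(n_null_sets):
        sets.append(
            GeneSet(
                name=f"null_{i:03d}",
                genes=list(rng.choice(noncausal, size=set_size, replace=False)),
                category=SetCategory.null,
                description="category=null",
            )
        )
    for i in range(n_null_sets):
        sets.append(
            GeneSet(
                name=f"null_nonspurious_{i:03d}",
                genes=list(
                    rng.choice(ns_noncausal, size=set_size, replace=False)
                ),
                category=SetCategory.null_nonspurious,
                description="category=null_nonspurious",
            )
        )
    for j, (c, chosen_causal) in enumerate(cat1_causal):
        chosen_non = list(
            rng.choice(ns_noncausal, size=set_size - c, replace=False)
        )
        sets.append(
            GeneSet(
                name=f"causal_mix_ns_C{c}_{j % sets_per_count:03d}",
                genes=chosen_causal + chosen_non,
                category=SetCategory.causal_mix_nonspurious,
                description=f"category=causal_mix_nonspurious C={c}",
            )
        )
    return sets


def set_features(
    gene_set: GeneSet,
    truth: TruthModel,
    gene_map: GeneMap,
    genotypes: GenotypeMatrix | None = None,
) -> SetFeatures:
    """Compute the five explanatory features for one set."""
    members = set(gene_set.genes)
    by_gene = gene_map.variants_by_gene()
    unknown = members - set(by_gene)
    if unknown:
        raise ValidationError(
            f"set {gene_set.name!r} has genes absent from the gene map "
            f"(first: {sorted(unknown)[0]!r})"
        )
    n_total = sum(len(by_gene[g]) for g in members)
    in_set = np.asarray(
        [g in members for g in truth.causal_variant_gene], dtype=bool
    )
    causal_genes_in = sorted(set(truth.causal_variant_gene[in_set]))
    if causal_genes_in:
        per_gene_sums = [
            truth.maf[in_set & (truth.causal_variant_gene == g)].sum()
            for g in causal_genes_in
        ]
        avg_maf = float(np.mean(per_gene_sums))
    else:
        avg_maf = 0.0
    return SetFeatures(
        n_causal_genes=len(causal_genes_in),
        n_causal_snps=int(in_set.sum()),
        n_total_snps=n_total,
        avg_maf_causal_genes=avg_maf,
        weighted_risk_score=float(
            (truth.maf[in_set] * truth.beta[in_set]).sum()
        ),
    )
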