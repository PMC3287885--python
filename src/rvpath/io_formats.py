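"""Readers and writers for the formats the toolkit touches.

Genotypes come in as VCF 4.x (via cyvcf2) or a plain TSV dialect
(individuals as rows, variant ids as columns, minor-allele dosage 0/1/2,
missing = "NA").  Gene sets use GMT, the SNP→gene map a two-column TSV,
phenotype replicates an individuals × replicates TSV.  Everything is
validated on construction; dosage values outside {0,1,2}, duplicated ids
and MAF inconsistencies are errors, not warnings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from rvpath._utils import (
    ParseError,
    UnsupportedRecordError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Sentinel for a missing dosage in the integer genotype matrix.
MISSING = -1


class SetCategory(str, Enum):
    """Provenance of an evaluation gene set."""

    causal_mix = "causal_mix"
    null = "null"
    null_nonspurious = "null_nonspurious"
    causal_mix_nonspurious = "causal_mix_nonspurious"
    user = "user"


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Individuals × variants minor-allele dosage matrix.

    ``dosages`` holds 0/1/2 counts of the minor allele with ``MISSING``
    (−1) for missing genotypes.  ``variant_maf`` is the in-sample minor
    allele frequency, recomputable from the dosages; a stored value more
    than 1e−9 away from the recomputed one fails validation.
    """

    individual_ids: list[str]
    variant_ids: list[str]
    dosages: np.ndarray
    variant_maf: np.ndarray
    variant_gene: np.ndarray

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    @classmethod
    def from_dosages(
        cls,
        individual_ids: Sequence[str],
        variant_ids: Sequence[str],
        dosages: np.ndarray,
        variant_gene: Sequence[str] | None = None,
    ) -> "GenotypeMatrix":
        """Build a validated matrix, computing MAF from the dosages."""
        dosages = np.asarray(dosages, dtype=np.int8)
        if variant_gene is None:
            variant_gene = [""] * len(variant_ids)
        gm = cls(
            individual_ids=list(individual_ids),
            variant_ids=list(variant_ids),
            dosages=dosages,
            variant_maf=_compute_maf(dosages),
            variant_gene=np.asarray(variant_gene, dtype=object),
        )
        gm.validate()
        return gm

    def recompute_maf(self) -> np.ndarray:
        return _compute_maf(self.dosages)

    def validate(self) -> None:
        n, m = self.dosages.shape
        if n != len(self.individual_ids) or m != len(self.variant_ids):
            raise ValidationError(
                f"dosage matrix {self.dosages.shape} does not match "
                f"{len(self.individual_ids)} individuals × "
                f"{len(self.variant_ids)} variants"
            )
        if len(set(self.individual_ids)) != n:
            raise ValidationError("individual ids are not unique")
        if len(set(self.variant_ids)) != m:
            raise ValidationError("variant ids are not unique")
        vals = self.dosages
        bad = ~np.isin(vals, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"dosage {vals[i, j]} at individual "
                f"{self.individual_ids[i]!r}, variant "
                f"{self.variant_ids[j]!r} is not in {{0,1,2}} or missing"
            )
        maf = self.recompute_maf()
        diff = np.abs(maf - np.asarray(self.variant_maf, dtype=float))
        if np.any(diff > 1e-9):
            j = int(np.argmax(diff))
            raise ValidationError(
                f"stored MAF {self.variant_maf[j]} for variant "
                f"{self.variant_ids[j]!r} differs from recomputed {maf[j]}"
            )

    def attach_gene_map(self, gene_map: "GeneMap") -> None:
        """Fill per-variant gene symbols from a map covering every variant."""
        missing = [v for v in self.variant_ids if v not in gene_map.mapping]
        if missing:
            raise ValidationError(
                f"gene map does not cover {len(missing)} variants "
                f"(first: {missing[0]!r})"
            )
        self.variant_gene = np.asarray(
            [gene_map.mapping[v] for v in self.variant_ids], dtype=object
        )


def _compute_maf(dosages: np.ndarray) -> np.ndarray:
    observed = dosages != MISSING
    n_obs = observed.sum(axis=0)
    if np.any(n_obs == 0):
        j = int(np.argmax(n_obs == 0))
        raise ValidationError(f"variant column {j} has no observed genotypes")
    counts = np.where(observed, dosages, 0).sum(axis=0)
    f = counts / (2.0 * n_obs)
    return np.minimum(f, 1.0 - f)


@dataclass
class PhenotypeReplicates:
    """Individuals × replicates binary disease-status matrix (1 = affected)."""

    individual_ids: list[str]
    status: np.ndarray

    @property
    def n_replicates(self) -> int:
        return self.status.shape[1]

    def validate(self) -> None:
        n, r = self.status.shape
        if n != len(self.individual_ids):
            raise ValidationError("status rows do not match individual ids")
        if not np.isin(self.status, (0, 1)).all():
            raise ValidationError("phenotype status must be 0/1")
        col_sums = self.status.sum(axis=0)
        if np.any(col_sums == 0) or np.any(col_sums == n):
            bad = int(np.argmax((col_sums == 0) | (col_sums == n)))
            raise ValidationError(
                f"replicate {bad} has no affected or no unaffected individuals"
            )

    def aligned_to(self, genotypes: GenotypeMatrix) -> "PhenotypeReplicates":
        """Reorder rows to match a genotype matrix's individuals exactly."""
        if set(self.individual_ids) != set(genotypes.individual_ids):
            raise ValidationError(
                "phenotype individuals do not match genotype individuals"
            )
        order = [self.individual_ids.index(i) for i in genotypes.individual_ids]
        out = PhenotypeReplicates(
            individual_ids=list(genotypes.individual_ids),
            status=self.status[order],
        )
        out.validate()
        return out


@dataclass
class GeneMap:
    """Variant → gene assignment; each variant belongs to exactly one gene."""

    mapping: dict[str, str]

    def genes(self) -> list[str]:
        return sorted(set(self.mapping.values()))

    def variants_by_gene(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for v, g in self.mapping.items():
            out.setdefault(g, []).append(v)
        return out

    def variant_indices_by_gene(
        self, genotypes: GenotypeMatrix
    ) -> dict[str, np.ndarray]:
        """Column indices of each gene's variants in a genotype matrix."""
        col = {v: j for j, v in enumerate(genotypes.variant_ids)}
        out: dict[str, list[int]] = {}
        for v in genotypes.variant_ids:
            if v not in self.mapping:
                raise ValidationError(f"variant {v!r} is not in the gene map")
            out.setdefault(self.mapping[v], []).append(col[v])
        return {g: np.asarray(idx, dtype=np.intp) for g, idx in out.items()}


@dataclass
class GeneSet:
    """A named collection of genes with a provenance category."""

    name: str
    genes: list[str]
    category: SetCategory = SetCategory.user
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(
                f"gene set {self.name!r} contains duplicate genes"
            )


# ---------------------------------------------------------------------------
# Genotype I/O
# ---------------------------------------------------------------------------


def read_genotypes(path: str | Path, format: str = "tsv") -> GenotypeMatrix:
    """Read a genotype matrix from ``tsv`` or ``vcf``.

    VCF GT fields are converted to minor-allele dosage: "0/1" and "1/0"
    → 1, "1/1" → 2, "./." → missing.  If the ALT allele is the major
    allele in-sample, dosages are recoded so they count the minor allele.
    Multi-allelic records are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        return _read_genotypes_tsv(path)
    if format == "vcf":
        return _read_genotypes_vcf(path)
    raise ValidationError(f"unknown genotype format {format!r}")


def _read_genotypes_tsv(path: Path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # noqa: BLE001 - wrap any pandas parse failure
        raise ParseError(f"{path}: could not parse TSV ({exc})") from exc
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no variant columns found")
    dosages = np.full(df.shape, MISSING, dtype=np.int8)
    values = df.to_numpy()
    for (i, j), raw in np.ndenumerate(values):
        if raw is None or (isinstance(raw, float) and np.isnan(raw)):
            continue
        s = str(raw).strip()
        if s in ("NA", ""):
            continue
        try:
            d = int(s)
        except ValueError as exc:
            raise ParseError(
                f"{path}: line {i + 2}: non-integer dosage {s!r}"
            ) from exc
        if d not in (0, 1, 2):
            raise ValidationError(
                f"{path}: line {i + 2}: dosage {d} outside {{0,1,2}}"
            )
        dosages[i, j] = d
    return GenotypeMatrix.from_dosages(
        [str(i) for i in df.index], [str(c) for c in df.columns], dosages
    )


def _read_genotypes_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"{path}: could not open VCF ({exc})") from exc
    individual_ids = list(vcf.samples)
    variant_ids: list[str] = []
    columns: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise UnsupportedRecordError(
                f"{path}: multi-allelic record at {rec.CHROM}:{rec.POS} "
                "is not supported"
            )
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
        col = np.full(len(individual_ids), MISSING, dtype=np.int8)
        for i, gt in enumerate(rec.genotypes):
            alleles = gt[:-1]
            if any(a < 0 for a in alleles):
                continue
            col[i] = sum(1 for a in alleles if a == 1)
        observed = col != MISSING
        if observed.sum() and col[observed].sum() > observed.sum():
            # ALT is the major allele in-sample; count the minor allele.
            col[observed] = 2 - col[observed]
        variant_ids.append(vid)
        columns.append(col)
    if not columns:
        raise ParseError(f"{path}: VCF contains no usable records")
    return GenotypeMatrix.from_dosages(
        individual_ids, variant_ids, np.column_stack(columns)
    )


def write_genotypes(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write the TSV dialect: individuals as rows, missing = NA."""
    df = pd.DataFrame(
        genotypes.dosages.astype(object),
        index=genotypes.individual_ids,
        columns=genotypes.variant_ids,
    )
    df = df.mask(genotypes.dosages == MISSING, "NA")
    df.to_csv(path, sep="\t", index_label="individual_id")


# ---------------------------------------------------------------------------
# Phenotype I/O
# ---------------------------------------------------------------------------


def read_phenotypes(path: str | Path) -> PhenotypeReplicates:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"{path}: could not parse TSV ({exc})") from exc
    status = df.to_numpy()
    if not np.issubdtype(status.dtype, np.number):
        raise ParseError(f"{path}: non-numeric phenotype entries")
    phen = PhenotypeReplicates(
        individual_ids=[str(i) for i in df.index],
        status=status.astype(np.int8),
    )
    phen.validate()
    return phen


def write_phenotypes(phenotypes: PhenotypeReplicates, path: str | Path) -> None:
    df = pd.DataFrame(
        phenotypes.status,
        index=phenotypes.individual_ids,
        columns=[f"rep{i}" for i in range(phenotypes.n_replicates)],
    )
    df.to_csv(path, sep="\t", index_label="individual_id")


# ---------------------------------------------------------------------------
# Gene sets (GMT) and gene map
# ---------------------------------------------------------------------------


def read_gene_sets(path: str | Path) -> list[GeneSet]:
    """Read GMT: one set per line — name, description, gene symbols."""
    path = Path(path)
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: expected ≥3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            name, description = fields[0], fields[1]
            if name in seen:
                raise ValidationError(
                    f"{path}: line {lineno}: duplicate set name {name!r}"
                )
            seen.add(name)
            genes: list[str] = []
            for g in fields[2:]:
                if not g:
                    continue
                if g in genes:
                    logger.warning(
                        "%s: line %d: duplicate gene %r in set %r dropped",
                        path, lineno, g, name,
                    )
                    continue
                genes.append(g)
            category = SetCategory.user
            if description.startswith("category="):
                label = description.split("=", 1)[1]
                try:
                    category = SetCategory(label)
                except ValueError:
                    pass
            sets.append(GeneSet(name, genes, category, description))
    if not sets:
        raise ParseError(f"{path}: empty GMT file")
    return sets


def write_gene_sets(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            desc = s.description or f"category={s.category.value}"
            fh.write("\t".join([s.name, desc, *s.genes]) + "\n")


def read_gene_map(path: str | Path) -> GeneMap:
    """Read the two-column TSV (variant_id, gene)."""
    path = Path(path)
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected 2 columns, "
                    f"got {len(fields)}"
                )
            variant, gene = fields
            if variant in mapping and mapping[variant] != gene:
                raise ValidationError(
                    f"{path}: line {lineno}: variant {variant!r} mapped to "
                    f"both {mapping[variant]!r} and {gene!r}"
                )
            mapping[variant] = gene
    if not mapping:
        raise ValidationError(f"{path}: empty gene map")
    return GeneMap(mapping)


def write_gene_map(gene_map: GeneMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for variant, gene in gene_map.mapping.items():
            fh.write(f"{variant}\t{gene}\n")


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

_RESULT_COLUMNS = ["unit_id", "method", "replicate", "statistic", "p_value"]
_SUMMARY_COLUMNS = ["set", "method", "alpha", "rate", "n_replicates"]


def write_results(results, path: str | Path) -> None:
    """Write test results or evaluation-summary rates as TSV.

    Accepts a non-empty list of TestResult-like objects (attributes
    unit_id, method, replicate, statistic, p_value) or an object with a
    ``rates`` DataFrame carrying the summary columns.  Floats are
    rendered at 6 significant digits.
    """
    rates = getattr(results, "rates", None)
    if rates is not None:
        if len(rates) == 0:
            raise ValidationError("empty evaluation summary")
        rates[_SUMMARY_COLUMNS].to_csv(
            path, sep="\t", index=False, float_format="%.6g"
        )
        return
    results = list(results)
    if not results:
        raise ValidationError("no results to write")
    rows = [
        {
            "unit_id": r.unit_id,
            "method": getattr(r.method, "value", r.method),
            "replicate": r.replicate,
            "statistic": r.statistic,
            "p_value": r.p_value,
        }
        for r in results
    ]
    pd.DataFrame(rows)[_RESULT_COLUMNS].to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def read_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(_RESULT_COLUMNS) - set(df.columns)
    if missing and set(_SUMMARY_COLUMNS) - set(df.columns):
        raise ParseError(f"{path}: unrecognized results columns")
    return df
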