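"""Link promoter signal to gene expression; compare gene-set expression.

Expression values are unit-agnostic: any nonnegative per-gene average
works.  Correlation is computed on log(1+x)-transformed values by
default, since both ChIP signal and expression are heavy-tailed; gene-set
comparison uses the Wilcoxon rank-sum test for the same reason (a t-test
is available).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .annotation import AnnotationError, _open_text
from .stats import pearson_r, ranksum_test, welch_ttest


class ExpressionTable(Mapping):
    """Mapping gene_id -> mean expression (nonnegative, finite)."""

    def __init__(self, values: Mapping[str, float]):
        for gid, v in values.items():
            if not math.isfinite(v):
                raise ValueError(f"non-finite expression for {gid}")
        self._values = dict(values)

    def __getitem__(self, k):
        return self._values[k]

    def __iter__(self):
        return iter(self._values)

    def __len__(self):
        return len(self._values)


def read_expression_tsv(path) -> ExpressionTable:
    """Read a two-column (gene_id, mean_expression) TSV, header optional."""
    values: dict[str, float] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise AnnotationError(f"{path}:{lineno}: expected 2 columns")
            if lineno == 1 and fields[0].lower() in ("gene_id", "gene"):
                continue
            gid = fields[0]
            if gid in values:
                raise AnnotationError(f"{path}:{lineno}: duplicate gene_id {gid}")
            values[gid] = float(fields[1])
    return ExpressionTable(values)


def write_expression_tsv(expr: ExpressionTable, path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("gene_id\tmean_expression\n")
        for gid in expr:
            fh.write(f"{gid}\t{expr[gid]:.6f}\n")


@dataclass(frozen=True)
class GeneSet:
    name: str
    gene_ids: frozenset[str]

    def __post_init__(self):
        if not self.gene_ids:
            raise ValueError(f"gene set {self.name!r} is empty")


def read_gene_set(path, name: str | None = None) -> GeneSet:
    """One gene id per line."""
    with _open_text(path) as fh:
        ids = frozenset(line.strip() for line in fh if line.strip())
    return GeneSet(name or str(path), ids)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    log_transformed: bool


def signal_expression_correlation(
    counts: Mapping[str, float],
    expr: ExpressionTable,
    log_transform: bool = True,
) -> CorrelationResult:
    """Pearson correlation between per-gene signal and mean expression,
    over the gene-id intersection (needs >= 3 genes)."""
    shared = sorted(set(counts) & set(expr))
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} genes shared between counts and expression")
    x = np.array([counts[g] for g in shared], dtype=float)
    y = np.array([expr[g] for g in shared], dtype=float)
    if log_transform:
        x = np.log1p(x)
        y = np.log1p(y)
    r = pearson_r(x, y)
    if math.isnan(r):
        warnings.warn("zero variance in signal or expression; correlation undefined")
    return CorrelationResult(r=r, n=len(shared), log_transformed=log_transform)


@dataclass(frozen=True)
class GeneSetComparison:
    name_a: str
    name_b: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    mean_a: float
    mean_b: float
    statistic: float
    p_value: float
    direction: str  # "a < b", "a > b" or "a ~ b"
    test: str


def gene_set_comparison(
    expr: ExpressionTable,
    set_a: GeneSet,
    set_b: GeneSet,
    test: str = "ranksum",
) -> GeneSetComparison:
    """Compare expression between two gene sets (two-sided).

    ``test`` is ``"ranksum"`` (Wilcoxon rank-sum, default) or
    ``"ttest"`` (Welch).  Both sets must intersect the table with >= 2
    genes each.
    """
    vals = {}
    for s in (set_a, set_b):
        v = np.array([expr[g] for g in sorted(s.gene_ids) if g in expr], dtype=float)
        if len(v) < 2:
            raise ValueError(f"gene set {s.name!r} shares < 2 genes with the table")
        vals[s.name] = v
    a, b = vals[set_a.name], vals[set_b.name]
    if test == "ranksum":
        res = ranksum_test(a, b)
        stat, p = res.statistic, res.p_value
    elif test == "ttest":
        res = welch_ttest(a, b)
        stat, p = res.t_statistic, res.p_value
    else:
        raise ValueError("test must be 'ranksum' or 'ttest'")
    med_a, med_b = float(np.median(a)), float(np.median(b))
    if med_a < med_b:
        direction = "a < b"
    elif med_a > med_b:
        direction = "a > b"
    else:
        direction = "a ~ b"
    return GeneSetComparison(
        name_a=set_a.name,
        name_b=set_b.name,
        n_a=len(a),
        n_b=len(b),
        median_a=med_a,
        median_b=med_b,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        statistic=stat,
        p_value=p,
        direction=direction,
        test=test,
    )
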