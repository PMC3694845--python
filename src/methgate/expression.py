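"""Expression-matrix normalization and moderated differential expression.

The statistical core is the empirical-Bayes moderated t-statistic: the
gene-wise pooled two-group variance ``s2_g`` (d residual df) is shrunk
toward a prior variance ``s0_sq`` with prior degrees of freedom ``d0``,

    s_tilde^2 = (d0 * s0_sq + d * s2_g) / (d0 + d)
    t_mod     = log2fc / (s_tilde * sqrt(1/n_a + 1/n_b))

with two-sided p-values from a Student t distribution on ``d0 + d``
degrees of freedom.  The hyperparameters are estimated by moment-matching
the marginal distribution of ``log s2_g``: under the scaled-inverse-chi2
prior, ``s2_g ~ s0_sq * F(d, d0)`` marginally, so

    E[log s2]   = log s0_sq + psi(d/2) - psi(d0/2) + log(d0/d)
    Var[log s2] = psi'(d/2) + psi'(d0/2)

where psi / psi' are the digamma / trigamma functions.  ``d0`` solves the
trigamma equation (Newton iteration); when the observed variance of
``log s2`` does not exceed ``psi'(d/2)`` the equations imply ``d0 = inf``
and the common variance (mean of ``s2_g``) is used for every gene.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import special, stats

logger = logging.getLogger("methgate")

__all__ = [
    "ExpressionMatrix",
    "ContrastSpec",
    "ContrastResult",
    "GeneSet",
    "quantile_normalize",
    "merge_probes_to_genes",
    "fit_moderated_t",
    "select_de_genes",
    "trigamma_inverse",
]


@dataclass
class ExpressionMatrix:
    """Log2 intensity matrix (rows = probes or genes, columns = samples)
    with a per-sample design annotation.

    ``design`` is indexed by sample id with columns genotype, treatment,
    time_h, replicate and context; it must cover exactly the value
    columns.
    """

    values: pd.DataFrame
    design: pd.DataFrame
    level: str = "probe"

    def __post_init__(self) -> None:
        if self.level not in ("probe", "gene"):
            raise ValueError("level must be 'probe' or 'gene'")
        if list(self.values.columns) != list(self.design.index):
            raise ValueError("value columns must match design rows (in order)")

    def select(self, **criteria) -> list[str]:
        """Sample ids matching all design criteria (scalars or lists)."""
        mask = pd.Series(True, index=self.design.index)
        for key, val in criteria.items():
            col = self.design[key]
            if isinstance(val, (list, tuple, set, frozenset)):
                mask &= col.isin(list(val))
            else:
                mask &= col == val
        return list(self.design.index[mask])


@dataclass(frozen=True)
class ContrastSpec:
    """A two-group comparison defined by design-column selectors.

    ``group_a`` and ``group_b`` map design columns to required values;
    log2 fold change is reported as mean(B) - mean(A), i.e. positive when
    expression is higher in group B.
    """

    group_a: Mapping[str, object]
    group_b: Mapping[str, object]
    label: str = ""


@dataclass
class ContrastResult:
    """Per-gene moderated statistics for one two-group contrast."""

    table: pd.DataFrame  # columns: log2fc, s2, t, p
    d0: float
    s0_sq: float
    d: int
    n_a: int
    n_b: int
    label: str = ""

    @property
    def log2fc(self) -> pd.Series:
        return self.table["log2fc"]

    @property
    def p(self) -> pd.Series:
        return self.table["p"]


@dataclass(frozen=True)
class GeneSet:
    label: str
    members: frozenset

    def __len__(self) -> int:
        return len(self.members)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the mean-of-sorted-columns reference
    distribution.

    Ties within a column receive the mean of the reference values across
    the whole tied rank run, so tied input values stay tied on output.
    """
    values = matrix.values
    arr = values.to_numpy(dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("expression matrix contains non-finite values")
    n, m = arr.shape
    order = np.argsort(arr, axis=0, kind="stable")
    reference = np.sort(arr, axis=0).mean(axis=1)

    out = np.empty_like(arr)
    for j in range(m):
        col_sorted_idx = order[:, j]
        col_sorted = arr[col_sorted_idx, j]
        if n < 2 or (col_sorted[1:] != col_sorted[:-1]).all():
            out[col_sorted_idx, j] = reference  # no ties: rank-wise map
            continue
        normalized_sorted = np.empty(n)
        i = 0
        while i < n:
            k = i
            while k + 1 < n and col_sorted[k + 1] == col_sorted[i]:
                k += 1
            normalized_sorted[i : k + 1] = reference[i : k + 1].mean()
            i = k + 1
        out[col_sorted_idx, j] = normalized_sorted
    return ExpressionMatrix(
        values=pd.DataFrame(out, index=values.index, columns=values.columns),
        design=matrix.design,
        level=matrix.level,
    )


def merge_probes_to_genes(
    matrix: ExpressionMatrix, probe_to_gene: pd.Series | Mapping[str, str]
) -> ExpressionMatrix:
    """Average probe rows of the same gene symbol into one gene row.

    Probes absent from the map (no gene symbol) are dropped.
    """
    if matrix.level != "probe":
        raise ValueError("matrix must be probe-level")
    mapping = pd.Series(probe_to_gene)
    if mapping.empty:
        raise ValueError("probe-to-gene map is empty")
    mapped = matrix.values.index.intersection(mapping.index)
    dropped = len(matrix.values.index) - len(mapped)
    if dropped:
        logger.info("merge_probes_to_genes: dropped %d unmapped probes", dropped)
    values = matrix.values.loc[mapped]
    genes = mapping.loc[mapped]
    merged = values.groupby(genes.to_numpy()).mean()
    merged.index.name = "gene"
    return ExpressionMatrix(values=merged, design=matrix.design, level="gene")


def trigamma_inverse(y: float, tol: float = 1e-12, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration).

    Returns inf for y <= 0 (no finite solution).
    """
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def _estimate_hyperparameters(s2: np.ndarray, d: int) -> tuple[float, float]:
    """Moment-match (d0, s0_sq) from gene-wise variances with d df each."""
    positive = s2[s2 > 0]
    if positive.size < 2:
        warnings.warn(
            "not enough positive gene variances; falling back to d0 = inf",
            RuntimeWarning,
        )
        return np.inf, float(s2.mean())
    z = np.log(positive)
    zvar = float(np.var(z, ddof=1))
    excess = zvar - float(special.polygamma(1, d / 2.0))
    if excess <= 0:
        return np.inf, float(s2.mean())
    d0 = 2.0 * trigamma_inverse(excess)
    log_s0 = (
        float(np.mean(z))
        - float(special.digamma(d / 2.0))
        + float(special.digamma(d0 / 2.0))
        - np.log(d0 / d)
    )
    return d0, float(np.exp(log_s0))


def fit_moderated_t(
    matrix: ExpressionMatrix, contrast: ContrastSpec
) -> ContrastResult:
    """Moderated two-group t-test for every gene of a gene-level matrix.

    Variances are pooled within the two contrasted groups only
    (d = n_a + n_b - 2 residual df per gene); hyperparameters are shared
    across genes.  If all genes have zero pooled variance the common
    variance fallback (d0 = inf) is used with a warning; a zero posterior
    variance then yields t = +/-inf (p = 0) for nonzero fold changes and
    t = 0 (p = 1) for zero fold changes.
    """
    cols_a = matrix.select(**contrast.group_a)
    cols_b = matrix.select(**contrast.group_b)
    if set(cols_a) & set(cols_b):
        raise ValueError(f"contrast groups overlap ({contrast.label!r})")
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError(
            f"each contrast group needs >= 2 samples "
            f"(got {len(cols_a)} vs {len(cols_b)} for {contrast.label!r})"
        )
    a = matrix.values[cols_a].to_numpy(dtype=float)
    b = matrix.values[cols_b].to_numpy(dtype=float)
    n_a, n_b = a.shape[1], b.shape[1]
    d = n_a + n_b - 2

    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    log2fc = mean_b - mean_a
    ss = ((a - mean_a[:, None]) ** 2).sum(axis=1) + (
        (b - mean_b[:, None]) ** 2
    ).sum(axis=1)
    s2 = ss / d

    if np.all(s2 == 0):
        warnings.warn(
            "all gene variances are zero; falling back to d0 = inf",
            RuntimeWarning,
        )
        d0, s0_sq = np.inf, 0.0
    else:
        d0, s0_sq = _estimate_hyperparameters(s2, d)

    if np.isinf(d0):
        s_tilde_sq = np.full_like(s2, s0_sq if s0_sq > 0 else float(s2.mean()))
        df_total = np.inf
    else:
        s_tilde_sq = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d0 + d

    se = np.sqrt(s_tilde_sq * (1.0 / n_a + 1.0 / n_b))
    t = np.divide(
        log2fc, se, out=np.zeros_like(log2fc, dtype=float), where=se > 0
    )
    t = np.where((se == 0) & (log2fc > 0), np.inf, t)
    t = np.where((se == 0) & (log2fc < 0), -np.inf, t)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, 0.0, 1.0)

    table = pd.DataFrame(
        {"log2fc": log2fc, "s2": s2, "t": t, "p": p}, index=matrix.values.index
    )
    return ContrastResult(
        table=table, d0=d0, s0_sq=s0_sq, d=d, n_a=n_a, n_b=n_b,
        label=contrast.label,
    )


def select_de_genes(
    result: ContrastResult,
    fc_fold: float = 2.0,
    p_max: float = 0.01,
    direction: str = "up",
) -> GeneSet:
    """Genes with p < p_max and signed linear fold change > fc_fold.

    Both inequalities are strict ("p value <0.01 and fold change >2 or
    4"): a gene at exactly fc_fold is excluded.  Direction 'up' selects
    genes higher in group B of the contrast.
    """
    if fc_fold <= 1:
        raise ValueError("fc_fold must be > 1")
    if direction not in ("up", "down"):
        raise ValueError(f"unknown direction {direction!r}")
    cut = np.log2(fc_fold)
    if direction == "up":
        fc_ok = result.table["log2fc"] > cut
    else:
        fc_ok = result.table["log2fc"] < -cut
    mask = fc_ok & (result.table["p"] < p_max)
    members = frozenset(result.table.index[mask])
    label = f"{result.label or 'contrast'}|{direction}{fc_fold:g}x"
    logger.info("select_de_genes: %s -> %d genes", label, len(members))
    return GeneSet(label=label, members=members)
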