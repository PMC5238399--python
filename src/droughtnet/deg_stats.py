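"""RPKM expression values and the exact Poisson tag-count test for DEGs.

The test models the number of unambiguous clean tags from a gene as Poisson.
Conditional on observing ``x`` tags in library 1 (total ``N1`` uniquely
aligned reads) the count ``y`` in library 2 (total ``N2``) follows

    p(y | x) = (N2/N1)^y * (x+y)! / (x! * y! * (1 + N2/N1)^(x+y+1)),

a negative-binomial law with ``x + 1`` failures and success probability
``N2/(N1+N2)``. A gene is called differentially expressed when the
BH-adjusted p-value is at or below ``fdr_max`` (default 0.001) *and* the
absolute log2 expression ratio is at least ``min_abs_log2`` (default 1).

Two-sided p-values use the doubled-CDF convention

    p = min(1, 2 * min(P(Y <= y), P(Y > y))),

which is exactly invariant under swapping the two libraries together with
their totals; see the methods note for the discrete-tail trade-offs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import betainc, gammaln
from statsmodels.stats.multitest import multipletests

from .core_io import SAMPLES, CountTable

__all__ = [
    "ComparisonGroup",
    "COMPARISON_GROUPS",
    "rpkm",
    "ac_term_probability",
    "deg_pvalue",
    "deg_pvalues",
    "bh_fdr",
    "call_degs",
]


@dataclass(frozen=True)
class ComparisonGroup:
    """An ordered pair of libraries tested against each other.

    The group ``RT-R`` (RT versus R) reports its fold change as
    log2(R/RT): ``numerator_sample`` is the second-named library.
    """

    name: str
    numerator_sample: str
    denominator_sample: str

    @classmethod
    def from_name(cls, name: str) -> "ComparisonGroup":
        if name not in _GROUP_NAMES:
            raise ValueError(f"unknown comparison group {name!r}; expected one of {_GROUP_NAMES}")
        first, second = name.split("-")
        return cls(name=name, numerator_sample=second, denominator_sample=first)

    @property
    def ratio_label(self) -> str:
        """Human-readable fold-change label, e.g. ``R/RT`` for group RT-R."""
        return f"{self.numerator_sample}/{self.denominator_sample}"


_GROUP_NAMES = ("RT-R", "S-R", "ST-RT", "ST-S")

#: The four comparison groups of the experimental design.
COMPARISON_GROUPS: dict[str, ComparisonGroup] = {
    n: ComparisonGroup.from_name(n) for n in _GROUP_NAMES
}


def rpkm(reads_on_gene: float, total_mapped_reads: float, gene_length_bases: float) -> float:
    """Reads per kilobase of gene per million mapped reads: 1e9*C/(N*L)."""
    if reads_on_gene < 0:
        raise ValueError("read count must be non-negative")
    if total_mapped_reads <= 0 or gene_length_bases <= 0:
        raise ValueError("library total and gene length must be positive")
    return 1e9 * reads_on_gene / (total_mapped_reads * gene_length_bases)


def ac_term_probability(y: int, x: int, N1: float, N2: float) -> float:
    """Probability term p(y|x) of the exact tag-count test, in log-space.

    Evaluated via log-gamma so counts of 1e4 and beyond do not overflow.
    """
    if y < 0 or x < 0:
        raise ValueError("counts must be non-negative")
    if N1 <= 0 or N2 <= 0:
        raise ValueError("library totals must be positive")
    r = N2 / N1
    logp = (
        y * math.log(r)
        + gammaln(x + y + 1)
        - gammaln(x + 1)
        - gammaln(y + 1)
        - (x + y + 1) * math.log1p(r)
    )
    return math.exp(logp)


def deg_pvalues(
    x: np.ndarray, y: np.ndarray, N1: float, N2: float
) -> np.ndarray:
    """Vectorised two-sided exact-test p-values for count arrays.

    ``P(Y <= y | x)`` is the CDF of a negative binomial with ``x+1`` failures
    and success probability ``N1/(N1+N2)``, i.e. the regularised incomplete
    beta function I_{N1/(N1+N2)}(x+1, y+1); no tail truncation is needed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("counts must be non-negative")
    if N1 <= 0 or N2 <= 0:
        raise ValueError("library totals must be positive")
    p1 = N1 / (N1 + N2)
    lower = betainc(x + 1.0, y + 1.0, p1)  # P(Y <= y)
    p = 2.0 * np.minimum(lower, 1.0 - lower)
    return np.minimum(p, 1.0)


def deg_pvalue(x: int, y: int, N1: float, N2: float) -> float:
    """Two-sided exact-test p-value for a single gene."""
    return float(deg_pvalues(np.array([x]), np.array([y]), N1, N2)[0])


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, order-aligned with input."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    table: CountTable,
    group: ComparisonGroup | str,
    fdr_max: float = 0.001,
    min_abs_log2: float = 1.0,
    rpkm_pseudocount: float = 0.001,
) -> pd.DataFrame:
    """Test every gene of ``table`` in one comparison group.

    Returns a frame indexed by gene_id with columns ``x`` and ``y`` (tag
    counts in the denominator and numerator libraries), ``rpkm_den`` /
    ``rpkm_num``, ``log2_ratio`` (log2 of numerator over denominator RPKM,
    pseudocount-stabilised), ``p_value``, ``fdr``, ``is_deg`` and
    ``direction`` (``up`` / ``down`` / ``none`` in the numerator sample).

    The FDR family is the full gene list of the table for this comparison.
    """
    if isinstance(group, str):
        group = ComparisonGroup.from_name(group)
    for s in (group.numerator_sample, group.denominator_sample):
        if s not in SAMPLES or s not in table.counts.columns:
            raise ValueError(f"unknown sample label {s!r}")

    num, den = group.numerator_sample, group.denominator_sample
    n_num = float(table.library_total[num])
    n_den = float(table.library_total[den])
    x = table.counts[den].to_numpy(dtype=float)
    y = table.counts[num].to_numpy(dtype=float)
    lengths = table.gene_length_bases.to_numpy(dtype=float)

    rpkm_den = 1e9 * x / (n_den * lengths)
    rpkm_num = 1e9 * y / (n_num * lengths)
    c = rpkm_pseudocount
    log2_ratio = np.log2((rpkm_num + c) / (rpkm_den + c))

    p = deg_pvalues(x, y, n_den, n_num)
    fdr = bh_fdr(p)
    is_deg = (fdr <= fdr_max) & (np.abs(log2_ratio) >= min_abs_log2)
    direction = np.where(~is_deg, "none", np.where(log2_ratio > 0, "up", "down"))

    return pd.DataFrame(
        {
            "x": x.astype(int),
            "y": y.astype(int),
            "rpkm_den": rpkm_den,
            "rpkm_num": rpkm_num,
            "log2_ratio": log2_ratio,
            "p_value": p,
            "fdr": fdr,
            "is_deg": is_deg,
            "direction": direction,
        },
        index=table.counts.index,
    )


def call_all_groups(
    table: CountTable,
    fdr_max: float = 0.001,
    min_abs_log2: float = 1.0,
    rpkm_pseudocount: float = 0.001,
) -> dict[str, pd.DataFrame]:
    """Run :func:`call_degs` for all four comparison groups."""
    return {
        name: call_degs(table, grp, fdr_max, min_abs_log2, rpkm_pseudocount)
        for name, grp in COMPARISON_GROUPS.items()
    }
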