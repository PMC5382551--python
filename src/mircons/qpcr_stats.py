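"""ddCt quantification and nonparametric statistics for qPCR data.

Crossing-point (Cp/Ct) values are reference-normalized per sample
(dCp = Cp_target - Cp_reference); group differences use the comparative
cycle-threshold method

    ddCt = mean(dCp_treated) - mean(dCp_control),   fold change = 2^(-ddCt).

Note the reversed scale: one expression doubling *lowers* Cp by one cycle, so
a higher dCp means lower expression.  All correlations on dCp are reported
with this convention stated: a positive Spearman rho against dCp is a
*negative* association with expression.

Group comparisons use the Mann-Whitney U test with an exact small-sample
branch: for n+m <= 12 the p-value is computed by full enumeration of all
C(n+m, n) group assignments on mid-ranks (so ties are handled exactly);
larger samples use the normal approximation with tie and continuity
correction.  Spearman rank correlation likewise switches from an exact
permutation p (n <= 8) to the t approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, permutations
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps

from .errors import AnalysisError, ConfigurationError

TREATED, CONTROL = "treated", "control"

DCP_SCALE_NOTE = "higher dCp means lower expression (reversed scale)"


@dataclass
class CpTable:
    """Sample x gene crossing-point values with group labels and a reference gene."""

    cp: pd.DataFrame                 # samples in rows, genes in columns
    group_labels: pd.Series          # sample -> {treated, control}
    reference_gene: str

    def __post_init__(self):
        if self.reference_gene not in self.cp.columns:
            raise ConfigurationError(
                f"reference gene {self.reference_gene!r} not measured"
            )
        missing = set(self.cp.index) - set(self.group_labels.index)
        if missing:
            raise ConfigurationError(f"samples without group label: {sorted(missing)}")


@dataclass
class DcpTable:
    """Reference-normalized Cp values; the reference gene's own dCp is 0."""

    dcp: pd.DataFrame
    group_labels: pd.Series
    reference_gene: str
    scale_note: str = DCP_SCALE_NOTE


@dataclass
class ConcordanceResult:
    """Cross-platform agreement of per-gene values (Spearman on the matched set)."""

    rho: float
    p: float
    n_matched: int
    matched_ids: list[str]
    excluded: dict[str, str] = field(default_factory=dict)   # id -> reason


def compute_dcp(cp: CpTable) -> DcpTable:
    """dCp = Cp_gene - Cp_reference per sample; missing Cp propagates as missing."""
    ref = cp.cp[cp.reference_gene]
    bad = ref.index[ref.isna()].tolist()
    if bad:
        raise ConfigurationError(
            f"reference gene {cp.reference_gene!r} missing in samples: {bad}"
        )
    dcp = cp.cp.sub(ref, axis=0)
    return DcpTable(dcp, cp.group_labels, cp.reference_gene)


def ddct_fold_change(dcp: DcpTable, gene: str) -> tuple[float, float]:
    """(ddCt, fold change 2^-ddCt) for one gene, treated vs control."""
    if gene not in dcp.dcp.columns:
        raise AnalysisError(f"gene {gene!r} not in dCp table")
    values = dcp.dcp[gene]
    groups = dcp.group_labels.reindex(values.index)
    t = values[groups == TREATED].dropna()
    c = values[groups == CONTROL].dropna()
    if t.empty or c.empty:
        raise AnalysisError(f"gene {gene!r}: empty treated or control group")
    ddct = float(t.mean() - c.mean())
    return ddct, float(2.0 ** -ddct)


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def mann_whitney(
    x: Sequence[float], y: Sequence[float], alternative: str = "two_sided"
) -> tuple[float, float]:
    """Mann-Whitney U (U counted for x) with exact enumeration when n+m <= 12.

    The exact branch enumerates all C(n+m, n) assignments of the pooled
    mid-ranks to the x group, so tied observations are handled without
    approximation.  ``alternative='less'`` tests x stochastically smaller.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise AnalysisError("mann_whitney requires non-empty samples")
    if alternative not in ("two_sided", "less", "greater"):
        raise AnalysisError(f"unknown alternative {alternative!r}")
    n, m = x.size, y.size
    ranks = _midranks(np.concatenate([x, y]))
    u_obs = float(ranks[:n].sum() - n * (n + 1) / 2)

    if n + m <= 12:
        total = comb(n + m, n)
        center = n * m / 2
        eps = 1e-9
        count = 0
        idx = range(n + m)
        for chosen in combinations(idx, n):
            u = ranks[list(chosen)].sum() - n * (n + 1) / 2
            if alternative == "two_sided":
                count += abs(u - center) >= abs(u_obs - center) - eps
            elif alternative == "less":
                count += u <= u_obs + eps
            else:
                count += u >= u_obs - eps
        return u_obs, count / total

    scipy_alt = {"two_sided": "two-sided", "less": "less", "greater": "greater"}
    res = sps.mannwhitneyu(x, y, alternative=scipy_alt[alternative],
                           method="asymptotic")
    return u_obs, float(res.pvalue)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rho on mid-ranks; exact permutation p for n <= 8, else t approx."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise AnalysisError(f"spearman requires >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise AnalysisError("spearman undefined for a constant vector")
    rx, ry = _midranks(x), _midranks(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if n <= 8:
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
        eps = 1e-12
        count = total = 0
        for perm in permutations(range(n)):
            r = float((rx_c * ry_c[list(perm)]).sum()) / denom
            count += abs(r) >= abs(rho) - eps
            total += 1
        return rho, count / total

    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1 - rho**2))
    return rho, float(2 * sps.t.sf(abs(t), df=n - 2))


def cross_platform_concordance(
    a: Mapping[str, float] | pd.Series, b: Mapping[str, float] | pd.Series
) -> ConcordanceResult:
    """Spearman concordance of two per-gene value maps on their shared ids.

    Ids missing from one platform are excluded with reason ``not_on_platform``;
    ids present but with a missing value (e.g. below the detection limit)
    are excluded with reason ``below_detection``.
    """
    a = pd.Series(a, dtype=float)
    b = pd.Series(b, dtype=float)
    excluded: dict[str, str] = {}
    for i in a.index.difference(b.index).union(b.index.difference(a.index)):
        excluded[i] = "not_on_platform"
    shared = a.index.intersection(b.index)
    matched = []
    for i in shared:
        if np.isnan(a[i]) or np.isnan(b[i]):
            excluded[i] = "below_detection"
        else:
            matched.append(i)
    if len(matched) < 3:
        raise AnalysisError(
            f"concordance undefined: only {len(matched)} matched ids"
        )
    rho, p = spearman(a[matched].to_numpy(), b[matched].to_numpy())
    return ConcordanceResult(rho, p, len(matched), list(matched), excluded)


def correlate_phenotype(
    dcp: DcpTable, phenotype: pd.Series, gene: str
) -> tuple[float, float]:
    """Spearman of a gene's dCp against a per-sample phenotype.

    Sign interpretation follows the dCp convention (see ``DcpTable.scale_note``):
    positive rho on dCp means the phenotype rises as *expression falls*.
    """
    if gene not in dcp.dcp.columns:
        raise AnalysisError(f"gene {gene!r} not in dCp table")
    shared = dcp.dcp.index.intersection(phenotype.index)
    if len(shared) < 3:
        raise AnalysisError("correlate_phenotype requires >= 3 overlapping samples")
    return spearman(dcp.dcp.loc[shared, gene].to_numpy(),
                    phenotype[shared].to_numpy())


def ddct_analysis(dcp: DcpTable) -> pd.DataFrame:
    """Per-gene ddCt table: ddct, fold_change, log2 fold change, U and p.

    Fold changes are emitted on both the linear (2^-ddCt) and log2 (-ddCt)
    scales.  The reference gene is included (its row is null by construction).
    """
    groups = dcp.group_labels.reindex(dcp.dcp.index)
    rows = []
    for gene in dcp.dcp.columns:
        ddct, fc = ddct_fold_change(dcp, gene)
        t = dcp.dcp.loc[groups == TREATED, gene].dropna().to_numpy()
        c = dcp.dcp.loc[groups == CONTROL, gene].dropna().to_numpy()
        if np.ptp(np.concatenate([t, c])) == 0:
            u, p = t.size * c.size / 2, 1.0
        else:
            u, p = mann_whitney(t, c)
        rows.append({"gene_id": gene, "ddct": ddct, "fold_change": fc,
                     "log2_fold_change": -ddct, "U": u, "p": p})
    return pd.DataFrame(rows)
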