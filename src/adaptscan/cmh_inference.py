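"""Replicate-stratified Cochran-Mantel-Haenszel scan with a drift-aware variance.

The classical CMH statistic for stratified 2x2 tables (strata = replicate
lines; rows = generation 1 vs 10; columns = alt vs ref allele) is

    T = ( sum_k (a_k - E_k) )^2 / sum_k V_k,

with ``a_k`` the generation-10 alt-allele count and ``E_k``, ``V_k`` the
hypergeometric mean and variance of that cell under the null of no frequency
change; ``T`` is referred to a chi-square with 1 df (no continuity
correction, so the statistic is exactly invariant to swapping allele labels).

The classical null only accounts for sampling of individuals. In an
evolve-and-resequence design the generation-10 frequency has also drifted for
``t`` Wright-Fisher generations at effective size Ne, adding
``p(1-p) * [1 - (1 - 1/(2 Ne))^t]`` to its variance. Propagated through the
numerator cell — ``a_k - E_k = (n1_k a_k - n10_k b_k) / N_k`` with ``b_k``
the generation-1 alt count, so a unit of drift variance in the generation-10
frequency enters scaled by ``(n1_k n10_k / N_k)^2`` — the drift-aware
denominator is

    V_k + (n1_k n10_k / N_k)^2 * phat_k (1 - phat_k) * [1 - (1 - 1/(2 Ne))^t],

where ``phat_k`` is the pooled stratum frequency, ``n1_k``/``n10_k`` the
per-generation allele counts. As Ne -> infinity the drift term vanishes and
the classical statistic is recovered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ConfigurationError


@dataclass
class CMHOptions:
    """Options for the CMH scan."""

    drift_aware: bool = True
    ne: int | None = None
    t_generations: int = 9
    fdr_alpha: float = 0.05
    window_bp: int = 2000

    def __post_init__(self):
        if self.ne is not None and self.ne < 2:
            raise ConfigurationError("ne must be >= 2")
        if self.t_generations < 1:
            raise ConfigurationError("t_generations must be >= 1")
        if not (0 < self.fdr_alpha < 1):
            raise ConfigurationError("fdr_alpha must lie in (0,1)")
        if self.window_bp < 1:
            raise ConfigurationError("window_bp must be >= 1")
        if self.drift_aware and self.ne is None:
            raise ConfigurationError("drift-aware mode requires ne")


def drift_variance_factor(ne: float, t_generations: int) -> float:
    """Fraction of p(1-p) accumulated as drift variance over t WF generations."""
    return 1.0 - (1.0 - 1.0 / (2.0 * ne)) ** t_generations


def cmh_scan(
    tables: np.ndarray,
    drift_aware: bool = False,
    ne: float | None = None,
    t_generations: int = 9,
):
    """Vectorized CMH statistic and p-value over many markers.

    ``tables`` has shape (n_markers, n_strata, 2, 2) with rows (gen1, gen10)
    and columns (alt, ref). Strata with a zero margin contribute nothing;
    markers monomorphic in every stratum get statistic 0 and p = 1.
    """
    tables = np.asarray(tables, dtype=float)
    if tables.ndim == 3:
        tables = tables[None]
    if (tables < 0).any():
        raise ConfigurationError("negative cell counts")
    if drift_aware and ne is None:
        raise ConfigurationError("drift-aware mode requires ne")

    b = tables[..., 0, 0]  # gen1 alt
    a = tables[..., 1, 0]  # gen10 alt
    n1 = tables[..., 0, :].sum(-1)
    n10 = tables[..., 1, :].sum(-1)
    m_alt = a + b
    N = n1 + n10
    valid = (n1 > 0) & (n10 > 0) & (m_alt > 0) & (m_alt < N)
    with np.errstate(invalid="ignore", divide="ignore"):
        E = n10 * m_alt / N
        V = n10 * n1 * m_alt * (N - m_alt) / (N**2 * (N - 1.0))
        if drift_aware:
            phat = m_alt / N
            V = V + (n1 * n10 / N) ** 2 * phat * (1 - phat) * drift_variance_factor(
                ne, t_generations
            )
    num = np.where(valid, a - E, 0.0).sum(axis=-1)
    den = np.where(valid, V, 0.0).sum(axis=-1)
    stat = np.where(den > 0, num**2 / np.where(den > 0, den, 1.0), 0.0)
    p = np.where(den > 0, stats.chi2.sf(stat, df=1), 1.0)
    return stat, p


def cmh_statistic(
    tables,
    drift_aware: bool = False,
    ne: float | None = None,
    t_generations: int = 9,
):
    """CMH statistic and p-value for a single marker (list of 2x2 strata)."""
    stat, p = cmh_scan(
        np.asarray(tables, dtype=float),
        drift_aware=drift_aware,
        ne=ne,
        t_generations=t_generations,
    )
    return float(stat[0]), float(p[0])


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1) | np.isnan(p)):
        raise ConfigurationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def assign_windows(chrom, pos, window_bp: int = 2000) -> np.ndarray:
    """Non-overlapping half-open windows anchored at coordinate 1.

    Position ``pos`` (1-based) falls in window ``(pos - 1) // window_bp`` of
    its chromosome, i.e. windows [1, 1+w), [1+w, 1+2w), ...
    """
    pos = np.asarray(pos, dtype=np.int64)
    idx = (pos - 1) // int(window_bp)
    return np.array([f"{c}:{i}" for c, i in zip(chrom, idx)], dtype=object)


def prune_windows(results: pd.DataFrame, window_bp: int = 2000) -> pd.DataFrame:
    """Mark the minimum-p marker of each 2-kb window as its representative.

    Requires columns chrom, pos, p_value; ties broken by smallest position.
    Adds ``window_id`` and boolean ``pruned_representative`` columns.
    """
    out = results.copy()
    if out.empty:
        out["window_id"] = pd.Series(dtype=object)
        out["pruned_representative"] = pd.Series(dtype=bool)
        return out
    out["window_id"] = assign_windows(out["chrom"], out["pos"], window_bp)
    order = out.sort_values(["window_id", "p_value", "pos"], kind="mergesort")
    best = order.groupby("window_id", sort=False).head(1).index
    out["pruned_representative"] = out.index.isin(best)
    return out


def significant_set(
    results: pd.DataFrame, fdr_alpha: float = 0.05
) -> pd.DataFrame:
    """BH-correct window representatives and flag significant markers.

    A marker is significant when it is its window's representative, its BH
    q-value is below ``fdr_alpha``, and its replicate deltas agree in sign
    (columns ``delta_rep*``): a change seen in only one replicate is treated
    as drift and discarded.
    """
    out = results.copy()
    out["q_value"] = np.nan
    rep_mask = out["pruned_representative"].to_numpy()
    if rep_mask.any():
        out.loc[rep_mask, "q_value"] = fdr_bh(out.loc[rep_mask, "p_value"])
    delta_cols = [c for c in out.columns if c.startswith("delta_rep")]
    if not delta_cols:
        raise ConfigurationError("no per-replicate delta columns found")
    deltas = out[delta_cols].to_numpy(float)
    consistent = (np.all(deltas > 0, axis=1)) | (np.all(deltas < 0, axis=1))
    out["replicate_consistent"] = consistent
    out["significant"] = rep_mask & (out["q_value"] < fdr_alpha) & consistent
    return out
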