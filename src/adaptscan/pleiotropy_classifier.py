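"""Antagonistic-pleiotropy / conditional-neutrality classification.

A marker that passed the significance and marker-effect filters is classified
from its per-replicate allele-frequency changes in the two soils:

* antagonistic pleiotropy (AP): |delta| > 0.1 in both soils, in opposite
  directions in the two soils, in both replicates individually (replicate
  deltas must agree in sign within each soil);
* conditional neutrality (CN): |delta| > 0.2 in one soil (either direction)
  but |delta| < 0.1 in the other, again in both replicates individually and
  with a single consistent "large-change" soil;
* OTHER: everything else.

All inequalities are strict; AP and CN are mutually exclusive by
construction (AP needs |delta| > 0.1 in both soils, CN needs |delta| < 0.1
in one). Markers are annotated to genes within a 1-kb flank, and AP
prevalence between treatments is compared with a binary (binomial) GLM
likelihood-ratio test alongside a Pearson chi-square on the 2x2 table.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError

AP_MIN = 0.1
CN_BIG = 0.2
CN_SMALL = 0.1


def classify_ap_cn(
    deltas_soil_a,
    deltas_soil_b,
    ap_min: float = AP_MIN,
    cn_big: float = CN_BIG,
    cn_small: float = CN_SMALL,
):
    """Classify one marker from per-replicate deltas in the two soils.

    Returns (class, cn_soil) with class in {"AP", "CN", "OTHER"} and cn_soil
    in {"A", "B", None} naming the large-change soil for CN calls.
    """
    da = np.asarray(deltas_soil_a, dtype=float)
    db = np.asarray(deltas_soil_b, dtype=float)
    if da.size == 0 or db.size == 0 or np.isnan(da).any() or np.isnan(db).any():
        raise ConfigurationError("missing replicate delta")

    def same_sign(d):
        return np.all(d > 0) or np.all(d < 0)

    ap = (
        np.all(np.abs(da) > ap_min)
        and np.all(np.abs(db) > ap_min)
        and same_sign(da)
        and same_sign(db)
        and np.sign(da[0]) != np.sign(db[0])
    )
    if ap:
        return "AP", None
    if np.all(np.abs(da) > cn_big) and np.all(np.abs(db) < cn_small):
        return "CN", "A"
    if np.all(np.abs(db) > cn_big) and np.all(np.abs(da) < cn_small):
        return "CN", "B"
    return "OTHER", None


def annotate_genes(
    chrom, pos: int, genes: pd.DataFrame, flank_bp: int = 1000
) -> list:
    """Genes overlapping [pos - flank, pos + flank] (1-based inclusive).

    ``genes`` needs columns gene_id, chrom, start, end. Unknown chromosome
    yields an empty list.
    """
    sub = genes[genes["chrom"] == chrom]
    if sub.empty:
        return []
    hit = (sub["start"] <= pos + flank_bp) & (sub["end"] >= pos - flank_bp)
    return sub.loc[hit, "gene_id"].tolist()


def _round_half_up(x: float, digits: int = 1) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(f"1e-{digits}"),
                                           rounding=ROUND_HALF_UP))


def class_percentage(count: int, n_significant: int):
    """Share of significant markers in a class, printed to one decimal."""
    if n_significant == 0:
        return None
    return _round_half_up(100.0 * count / n_significant, 1)


def summarize_classes(calls: pd.DataFrame, n_significant: dict) -> pd.DataFrame:
    """Per-treatment counts, percentages and AP gene tally.

    ``calls`` needs columns treatment, class and (optionally) genes;
    ``n_significant`` maps treatment -> significant-marker denominator.
    """
    rows = []
    for trt, sub in calls.groupby("treatment", sort=False):
        denom = int(n_significant.get(trt, 0))
        ap = sub[sub["class"] == "AP"]
        cn = sub[sub["class"] == "CN"]
        genes = set()
        if "genes" in ap.columns:
            for gl in ap["genes"]:
                genes.update(gl if isinstance(gl, (list, tuple, set)) else [])
        rows.append(
            {
                "treatment": trt,
                "n_significant": denom,
                "n_ap": len(ap),
                "pct_ap": class_percentage(len(ap), denom),
                "n_cn": len(cn),
                "pct_cn": class_percentage(len(cn), denom),
                "n_other": int((sub["class"] == "OTHER").sum()),
                "n_ap_genes": len(genes),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PrevalenceTest:
    """AP-prevalence comparison between two treatments."""

    lr_stat: float
    lr_p: float
    pearson_chi2: float
    pearson_p: float


def _binom_ll(k: np.ndarray, n: np.ndarray, p: np.ndarray) -> float:
    k, n, p = (np.asarray(v, dtype=float) for v in (k, n, p))
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(k > 0, k * np.log(p), 0.0)
        term2 = np.where(n - k > 0, (n - k) * np.log(1 - p), 0.0)
    return float(np.sum(term1 + term2))


def compare_prevalence(count_a: int, total_a: int,
                       count_b: int, total_b: int) -> PrevalenceTest:
    """Test equality of two proportions (AP markers / significant markers).

    The 1-df likelihood-ratio statistic is the deviance drop of the binary
    GLM with treatment as the only factor (closed form for a 2x2 binomial,
    stable even under complete separation); a Pearson chi-square on the same
    table is reported alongside.
    """
    if total_a <= 0 or total_b <= 0:
        raise ConfigurationError("totals must be positive")
    if count_a > total_a or count_b > total_b:
        raise ConfigurationError("count exceeds total")
    k = np.array([count_a, count_b], dtype=float)
    n = np.array([total_a, total_b], dtype=float)
    p_hat = np.where(n > 0, k / n, 0.0)
    p_pool = k.sum() / n.sum()
    lr = 2.0 * (_binom_ll(k, n, p_hat) - _binom_ll(k, n, np.full(2, p_pool)))
    lr = max(lr, 0.0)
    lr_p = float(stats.chi2.sf(lr, df=1))
    table = np.array([[count_a, total_a - count_a],
                      [count_b, total_b - count_b]])
    if np.all(table.sum(axis=0) > 0) and np.all(table.sum(axis=1) > 0):
        chi2, chi2_p = stats.chi2_contingency(table, correction=False)[:2]
    else:
        chi2, chi2_p = 0.0, 1.0
    return PrevalenceTest(lr, lr_p, float(chi2), float(chi2_p))


def classify_group(
    scan_soil_a: pd.DataFrame,
    scan_soil_b: pd.DataFrame,
    retained_a=None,
    retained_b=None,
    genes: pd.DataFrame | None = None,
    ap_min: float = AP_MIN,
    cn_big: float = CN_BIG,
    cn_small: float = CN_SMALL,
    strict_cn: bool = False,
    flank_bp: int = 1000,
) -> pd.DataFrame:
    """Classify every candidate marker of one pollination x herbivory group.

    ``scan_soil_*`` are per-treatment scan tables (one row per marker, from
    :func:`adaptscan.cmh_inference.significant_set`) for the group's two soil
    treatments; ``retained_*`` optionally restrict to markers with a marker
    effect in both replicates of that soil's model. Candidates are markers
    significant in at least one soil. AP calls additionally require
    significance in BOTH soils (a marker significant in only one soil is
    discarded from the AP path); CN calls require significance in the
    large-change soil, or in both when ``strict_cn`` is set.
    """
    a = scan_soil_a.set_index("marker_id")
    b = scan_soil_b.set_index("marker_id")
    common = a.index.intersection(b.index)
    a, b = a.loc[common], b.loc[common]
    delta_cols = [c for c in a.columns if c.startswith("delta_rep")]
    sig_a = a["significant"].to_numpy(bool)
    sig_b = b["significant"].to_numpy(bool)
    if retained_a is not None:
        sig_a &= common.isin(set(np.asarray(retained_a).tolist()))
    if retained_b is not None:
        sig_b &= common.isin(set(np.asarray(retained_b).tolist()))

    rows = []
    for i, mk in enumerate(common):
        if not (sig_a[i] or sig_b[i]):
            continue
        da = a.loc[mk, delta_cols].to_numpy(float)
        db = b.loc[mk, delta_cols].to_numpy(float)
        cls, cn_soil = classify_ap_cn(da, db, ap_min, cn_big, cn_small)
        if cls == "AP" and not (sig_a[i] and sig_b[i]):
            cls, cn_soil = "OTHER", None
        if cls == "CN":
            need = (sig_a[i] and sig_b[i]) if strict_cn else (
                sig_a[i] if cn_soil == "A" else sig_b[i]
            )
            if not need:
                cls, cn_soil = "OTHER", None
        gene_ids = (
            annotate_genes(a.loc[mk, "chrom"], int(a.loc[mk, "pos"]), genes,
                           flank_bp)
            if genes is not None
            else []
        )
        rows.append(
            {
                "marker_id": mk,
                "chrom": a.loc[mk, "chrom"],
                "pos": int(a.loc[mk, "pos"]),
                "class": cls,
                "cn_soil": cn_soil,
                "delta_soil_a": float(np.mean(da)),
                "delta_soil_b": float(np.mean(db)),
                "significant_a": bool(sig_a[i]),
                "significant_b": bool(sig_b[i]),
                "genes": gene_ids,
            }
        )
    columns = ["marker_id", "chrom", "pos", "class", "cn_soil", "delta_soil_a",
               "delta_soil_b", "significant_a", "significant_b", "genes"]
    return pd.DataFrame(rows, columns=columns)
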