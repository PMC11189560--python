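"""Allele frequencies, generation-1 to generation-10 change, and CMH count tables.

Frequencies are always polarized on the alt allele of the marker map and
computed from called (non-missing) genotypes only; the allele-frequency change
of a treatment x replicate is ``p_gen10 - p_gen1``. Stratified 2x2 count
tables (rows: generation 1/10, columns: alt/ref allele counts, one stratum
per replicate) feed the Cochran-Mantel-Haenszel test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError


def allele_freq(dosages: np.ndarray, sample_mask=None) -> np.ndarray:
    """Alt-allele frequency per marker: sum(dosage) / (2 x non-missing count).

    Markers with no called genotype get ``nan``.
    """
    dosages = np.asarray(dosages, dtype=float)
    if sample_mask is not None:
        sample_mask = np.asarray(sample_mask)
        if sample_mask.sum() == 0:
            raise ConfigurationError("empty sample mask")
        dosages = dosages[sample_mask]
    called = np.sum(~np.isnan(dosages), axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.nansum(dosages, axis=0) / (2.0 * called)
    return np.where(called > 0, freq, np.nan)


def allele_counts(dosages: np.ndarray):
    """Per-marker (alt, ref) allele counts from non-missing diploid calls."""
    dosages = np.asarray(dosages, dtype=float)
    called = np.sum(~np.isnan(dosages), axis=0)
    alt = np.nansum(dosages, axis=0)
    ref = 2.0 * called - alt
    return alt.astype(np.int64), ref.astype(np.int64)


def af_change(
    gen1_dosages: np.ndarray,
    gen10_dosages: np.ndarray,
    markers: pd.DataFrame,
    treatment: str,
    replicate: str,
) -> pd.DataFrame:
    """Per-marker allele-frequency change table for one treatment x replicate."""
    for name, d in (("generation 1", gen1_dosages), ("generation 10", gen10_dosages)):
        if d is None or np.size(d) == 0:
            raise ConfigurationError(
                f"{name} genotypes missing for {treatment} replicate {replicate}"
            )
    p1 = allele_freq(gen1_dosages)
    p10 = allele_freq(gen10_dosages)
    n1 = 2 * np.sum(~np.isnan(np.asarray(gen1_dosages, float)), axis=0)
    n10 = 2 * np.sum(~np.isnan(np.asarray(gen10_dosages, float)), axis=0)
    return pd.DataFrame(
        {
            "marker_id": markers["marker_id"].to_numpy(),
            "chrom": markers["chrom"].to_numpy(),
            "pos": markers["pos"].to_numpy(),
            "treatment": treatment,
            "replicate": replicate,
            "p_gen1": p1,
            "p_gen10": p10,
            "delta": p10 - p1,
            "n_gen1": n1,
            "n_gen10": n10,
        }
    )


def mean_af_change(table: pd.DataFrame, n_replicates: int = 2) -> pd.DataFrame:
    """Mean replicate delta per marker x treatment.

    Markers observed (non-nan delta) in fewer than ``n_replicates`` replicates
    are flagged ``excluded`` and must not be used downstream — a change seen
    in a single replicate is indistinguishable from drift.
    """
    ok = table.dropna(subset=["delta"])
    grouped = ok.groupby(["marker_id", "treatment"], sort=False).agg(
        chrom=("chrom", "first"),
        pos=("pos", "first"),
        mean_delta=("delta", "mean"),
        n_replicates=("replicate", "nunique"),
    )
    grouped["excluded"] = grouped["n_replicates"] < n_replicates
    return grouped.reset_index()


def build_count_tables(
    gen1_by_replicate: dict, gen10_by_replicate: dict
) -> np.ndarray:
    """Stack per-replicate 2x2 allele-count tables for every marker.

    Parameters are mappings replicate label -> dosage matrix. Returns an
    integer array of shape (n_markers, n_replicates, 2, 2) with rows
    (generation 1, generation 10) and columns (alt, ref).
    """
    reps = sorted(gen1_by_replicate)
    if sorted(gen10_by_replicate) != reps or not reps:
        raise ConfigurationError("generation 1/10 replicate sets differ or are empty")
    per_rep = []
    for rep in reps:
        a1, r1 = allele_counts(gen1_by_replicate[rep])
        a10, r10 = allele_counts(gen10_by_replicate[rep])
        per_rep.append(np.stack([np.stack([a1, r1], -1), np.stack([a10, r10], -1)], 1))
    return np.stack(per_rep, axis=1)
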