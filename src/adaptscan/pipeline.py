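"""End-to-end orchestration: simulator bundle -> scans -> effects -> AP/CN calls.

Per treatment (soil x herbivory x pollination) the scan builds replicate
count tables between generations 1 and 10, runs the drift-aware CMH test
with the treatment's configured Ne, prunes 2-kb windows, BH-corrects the
representatives and applies the replicate-direction consistency rule. Per
treatment x replicate a ridge-BLUP model of the fitness-proxy trait is
fitted on the reciprocal-transplant plants (local- and foreign-grown,
generation 10 only, 60% training split), and markers lacking an effect in
either replicate are discarded. Classification then pairs the two soils of
each pollination x herbivory group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import allele_dynamics, cmh_inference, marker_effects, pleiotropy_classifier
from .exceptions import ConfigurationError
from .synthetic_experiment import ExperimentResult, SOILS, treatment_label


def scan_treatment(
    result: ExperimentResult,
    treatment: str,
    opts: cmh_inference.CMHOptions | None = None,
) -> pd.DataFrame:
    """CMH scan table for one treatment: statistic, p, q, window, deltas."""
    config = result.config
    final_gen = config.final_generation
    reps = sorted({r for (t, r, g) in result.genotypes if t == treatment})
    if not reps:
        raise ConfigurationError(f"no genotypes for treatment {treatment}")
    ne = config.ne_per_treatment[treatment]
    opts = opts or cmh_inference.CMHOptions(ne=ne)
    gen1 = {r: result.dosages(treatment, r, 1) for r in reps}
    gen10 = {r: result.dosages(treatment, r, final_gen) for r in reps}
    tables = allele_dynamics.build_count_tables(gen1, gen10)
    stat, p = cmh_inference.cmh_scan(
        tables,
        drift_aware=opts.drift_aware,
        ne=opts.ne if opts.ne is not None else ne,
        t_generations=opts.t_generations,
    )
    scan = result.markers[["marker_id", "chrom", "pos"]].copy()
    scan["treatment"] = treatment
    scan["statistic"] = stat
    scan["p_value"] = p
    for r in reps:
        delta = allele_dynamics.allele_freq(gen10[r]) - allele_dynamics.allele_freq(
            gen1[r]
        )
        scan[f"delta_rep{r}"] = delta
    scan = cmh_inference.prune_windows(scan, opts.window_bp)
    return cmh_inference.significant_set(scan, opts.fdr_alpha)


def fit_treatment_effects(
    result: ExperimentResult,
    treatment: str,
    trait: str = "open_flowers",
    train_fraction: float = 0.6,
    rng: np.random.Generator | None = None,
) -> dict:
    """Ridge-BLUP marker-effect models per replicate of one treatment.

    Uses the reciprocal-transplant phenotypes of generation-10 plants (grown
    in local and foreign soil) with the trait Z-transformed within each
    treatment x replicate data set and a 60% training split.
    """
    rng = rng or np.random.default_rng(0)
    config = result.config
    final_gen = config.final_generation
    tab = result.transplant
    tab = tab[(tab["treatment"] == treatment) & (tab["generation"] == final_gen)]
    models = {}
    for rep, sub in tab.groupby("replicate", sort=True):
        dosages = result.dosages(treatment, rep, final_gen)
        X = dosages[sub["plant_index"].to_numpy()]
        coded, kept_ids, _ = marker_effects.prepare_matrix(
            X, result.markers["marker_id"].to_numpy()
        )
        y = marker_effects.z_transform(sub[trait].to_numpy(float))
        row_ids = np.arange(len(sub))
        train, _hold = marker_effects.train_split(
            row_ids, fraction=train_fraction, rng=rng
        )
        train = np.asarray(train)
        models[(treatment, rep)] = marker_effects.fit_ridge_blup(
            coded[train], y[train], marker_ids=kept_ids,
            training_ids=sub["plant_id"].to_numpy()[train].tolist(),
        )
    return models


@dataclass
class GroupAnalysis:
    """Classification output for one pollination x herbivory group."""

    biotic_group: str
    soil_a: str
    soil_b: str
    scan_a: pd.DataFrame
    scan_b: pd.DataFrame
    calls: pd.DataFrame
    n_significant: dict = field(default_factory=dict)


def analyze_group(
    result: ExperimentResult,
    herbivory: bool,
    pollination: str,
    genes: pd.DataFrame | None = None,
    opts: cmh_inference.CMHOptions | None = None,
    with_effects: bool = True,
    trait: str = "open_flowers",
    rng: np.random.Generator | None = None,
    strict_cn: bool = False,
) -> GroupAnalysis:
    """Scan both soils of a biotic group, fit effects, classify AP/CN."""
    rng = rng or np.random.default_rng(0)
    soil_a, soil_b = SOILS
    label_a = treatment_label(soil_a, herbivory, pollination)
    label_b = treatment_label(soil_b, herbivory, pollination)

    def build(label):
        scan = scan_treatment(result, label, opts)
        retained = None
        if with_effects:
            models = fit_treatment_effects(result, label, trait=trait, rng=rng)
            (_, ma), (_, mb) = sorted(models.items())[0], sorted(models.items())[-1]
            retained = marker_effects.cross_replicate_retain(ma, mb)
        return scan, retained

    scan_a, retained_a = build(label_a)
    scan_b, retained_b = build(label_b)
    calls = pleiotropy_classifier.classify_group(
        scan_a,
        scan_b,
        retained_a,
        retained_b,
        genes=genes,
        strict_cn=strict_cn,
    )
    biotic = ("H" if herbivory else "NH") + ("B" if pollination == "bee" else "H")
    calls.insert(1, "treatment", biotic)
    n_sig = {
        label_a: int(scan_a["significant"].sum()),
        label_b: int(scan_b["significant"].sum()),
        biotic: int(scan_a["significant"].sum() + scan_b["significant"].sum()),
    }
    return GroupAnalysis(biotic, label_a, label_b, scan_a, scan_b, calls, n_sig)


def evaluate_against_truth(analysis: GroupAnalysis, truth: pd.DataFrame) -> dict:
    """Ground-truth recovery summary for one analyzed group.

    Reports, among true-AP loci that reached significance in both soils, the
    fraction classified AP; and the fraction of true-neutral loci that
    received any AP or CN label.
    """
    truth = truth.set_index("marker_id")
    calls = analysis.calls.set_index("marker_id")
    sig_both = calls.index[
        calls["significant_a"].astype(bool) & calls["significant_b"].astype(bool)
    ]
    ap_true = truth.index[truth["locus_class"] == "AP"]
    ap_sig = [m for m in ap_true if m in sig_both]
    ap_recovered = [m for m in ap_sig if calls.loc[m, "class"] == "AP"]
    neutral = truth.index[truth["locus_class"] == "NEUTRAL"]
    neutral_labelled = [
        m
        for m in neutral
        if m in calls.index and calls.loc[m, "class"] in ("AP", "CN")
    ]
    return {
        "n_true_ap": int(len(ap_true)),
        "n_true_ap_significant": int(len(ap_sig)),
        "ap_recovery": (len(ap_recovered) / len(ap_sig)) if ap_sig else np.nan,
        "n_neutral": int(len(neutral)),
        "neutral_mislabel_rate": (
            len(neutral_labelled) / len(neutral) if len(neutral) else np.nan
        ),
    }
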