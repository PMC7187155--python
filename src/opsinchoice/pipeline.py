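"""End-to-end orchestration: simulate -> quantify -> filter -> genotype
-> score -> associate, with every intermediate table and a discard
ledger written to disk."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import association, filtering, genotyping, preference, qpcr, synthetic


def run_all(plan: synthetic.SimulationPlan, outdir,
            window_cfg: qpcr.WindowConfig = qpcr.WindowConfig()) -> dict:
    """Run the whole pipeline on a simulated study; returns a results dict.

    Writes: the simulated inputs, per-reaction fits, QC report,
    expression profiles (raw and filtered), the removal/discard ledger,
    genotype calls and tallies, trial scores, per-female means, the
    association summaries and a JSON overview.
    """
    out = Path(outdir)
    datadir = synthetic.write_dataset(plan, out / "data")
    cohort = pd.read_csv(datadir / "samples.csv")

    # --- quantify ---------------------------------------------------------
    curves = pd.read_csv(datadir / "curves.csv")
    meta = cohort.rename(columns={"female_id": "sample"})
    profiles, qc_report, fits = qpcr.quantify(curves, meta, window_cfg)
    profiles.to_csv(out / "profiles.csv", index=False)
    qc_report.to_csv(out / "qc_report.csv", index=False)
    fits.to_csv(out / "fits.csv", index=False)

    # --- filter -----------------------------------------------------------
    complete = profiles[profiles["complete"]].reset_index(drop=True)
    filtered, report = filtering.iqr_filter(complete)
    filtered.to_csv(out / "profiles_filtered.csv", index=False)
    report.as_frame().to_csv(out / "removals.csv", index=False)

    discards = []
    for _, row in profiles[~profiles["complete"]].iterrows():
        discards.append({"stage": "qpcr_qc", "sample": row["sample"],
                         "reason": "incomplete_profile"})
    for rem in report.removals:
        discards.append({"stage": "iqr_filter", "sample": rem.sample_id,
                         "reason": "outlier:" + ",".join(rem.genes)})

    # --- genotype ---------------------------------------------------------
    calls = genotyping.call_fasta(datadir / "lws.fasta", plan.layout)
    pedigree = pd.read_csv(datadir / "pedigree.csv")
    calls = genotyping.pedigree_impute(calls, pedigree)
    meta_g = cohort[["female_id", "species", "rearing_light"]]
    tally, unjoined = genotyping.tally_genotypes(calls, meta_g)
    genotyping.calls_to_frame(calls).to_csv(out / "genotypes.csv", index=False)
    tally.to_csv(out / "genotype_tally.csv", index=False)

    # --- score ------------------------------------------------------------
    trials_df = pd.read_csv(datadir / "trials.csv")
    events_df = pd.read_csv(datadir / "events.csv")
    trials = preference.parse_trials(trials_df, events_df)
    scores = preference.score_trials(trials)
    scores.to_csv(out / "scores.csv", index=False)
    means = preference.mean_preference(scores)
    means.to_csv(out / "mean_preference.csv", index=False)
    for _, row in scores[~scores["valid"]].iterrows():
        discards.append({"stage": "trial_validity", "sample": row["trial_id"],
                         "reason": row["reasons"]})
    pd.DataFrame(discards).to_csv(out / "discard_ledger.csv", index=False)

    # --- repeatability ----------------------------------------------------
    valid = scores[scores["valid"]].dropna(subset=["pref_LD"])
    rep = preference.repeatability(valid["pref_LD"], valid["female_id"])

    # --- associate --------------------------------------------------------
    results = {}
    # expression ~ light*species*sex (LWS; sex constant in the all-female
    # cohort, so the model drops to light*species)
    expr = filtered.copy()
    fixed = ("rearing_light*species*sex" if expr["sex"].nunique() > 1
             else "rearing_light*species")
    m_expr = association.AssociationModel(
        expr, "prop_LWS", fixed,
        random_candidates=("dam_id", "sire_id"),
        covariate_candidates=("age_days",))
    r_expr = m_expr.fit()
    results["expression_LWS"] = r_expr
    (out / "association_expression.txt").write_text(r_expr.summary() + "\n")

    # preference ~ genotype*rearing light*test light, female/observer random
    geno_map = {fid: c.genotype for fid, c in calls.items()}
    pref = scores[scores["valid"]].copy()
    pref["genotype"] = pref["female_id"].map(geno_map)
    pref["species"] = pref["female_id"].map(
        cohort.set_index("female_id")["species"])
    pref["rearing_light"] = pref["female_id"].map(
        cohort.set_index("female_id")["rearing_light"])
    pref = pref.dropna(subset=["pref_LD", "genotype"])
    m_pref = association.AssociationModel(
        pref, "pref_LD", "genotype*rearing_light*test_light",
        random_candidates=("female_id", "observer_id"))
    r_pref = m_pref.fit()
    results["preference_genotype"] = r_pref
    (out / "association_preference.txt").write_text(r_pref.summary() + "\n")

    comparison = association.interaction_comparison(pref)
    comparison.to_csv(out / "interaction_comparison.csv", index=False)

    corr = association.preference_expression_correlation(
        preference.mean_preference(scores), filtered)
    corr.to_csv(out / "preference_expression_correlation.csv", index=False)

    overview = {
        "n_samples_quantified": int(profiles["complete"].sum()),
        "n_samples_filtered_out": report.n_removed,
        "n_samples_retained": int(len(filtered)),
        "n_genotyped": len(calls),
        "n_trials": int(len(scores)),
        "n_valid_trials": int(scores["valid"].sum()),
        "repeatability_LD": rep.R,
        "expression_mam": r_expr.mam_formula,
        "preference_mam": r_pref.mam_formula,
        "interaction_p_genotype": float(comparison["p"].iloc[0]),
        "interaction_p_species": float(comparison["p"].iloc[1]),
    }
    (out / "overview.json").write_text(json.dumps(overview, indent=2) + "\n")
    results.update(overview=overview, scores=scores, filtered=filtered,
                   tally=tally, repeatability=rep, comparison=comparison,
                   correlations=corr)
    return results
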