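"""Lane normalization, peptide aggregation, and the filter cascades."""

import numpy as np
import pandas as pd
import pytest

from cwpquant import (PipelineConfig, SimulationConfig, aggregate_peptides,
                      filter_peptides, lane_totals, normalize_lanes,
                      quantify_proteins, simulate_experiment)


def test_lane_totals_toy(toy_obs):
    obs = toy_obs([("A", 2, 100.0, "P1", "9DAF", 1, 3, 5.0),
                   ("B", 2, 200.0, "P1", "9DAF", 1, 7, 7.0),
                   ("A", 2, 100.0, "P1", "13DAF", 1, 3, 4.0)])
    totals = lane_totals(obs)
    assert totals[("9DAF", 1)] == 12.0
    assert totals[("13DAF", 1)] == 4.0
    assert ("9DAF", 2) not in totals.index
    shuffled = lane_totals(obs.iloc[::-1].reset_index(drop=True))
    pd.testing.assert_series_equal(totals.sort_index(),
                                   shuffled.sort_index())


def test_normalization_factors_from_totals(toy_obs):
    obs = toy_obs([("A", 2, 100.0, "P1", "9DAF", 1, 1, 30.0),
                   ("B", 2, 200.0, "P1", "9DAF", 1, 2, 70.0),
                   ("A", 2, 100.0, "P1", "9DAF", 2, 1, 300.0)])
    out = normalize_lanes(obs)
    # totals {100, 300}, mean 200 -> factors {2.0, 2/3}
    first = out[(out["stage"] == "9DAF") & (out["replicate"] == 1)]
    assert sorted(first["xic"]) == [60.0, 140.0]
    second = out[out["replicate"] == 2]
    assert second["xic"].iloc[0] == pytest.approx(200.0)
    totals = lane_totals(out)
    assert totals.max() - totals.min() < 1e-9 * totals.mean()


def test_normalization_identity_cases(toy_obs):
    equal = toy_obs([("A", 2, 100.0, "P1", "9DAF", 1, 1, 50.0),
                     ("A", 2, 100.0, "P1", "9DAF", 2, 1, 50.0)])
    pd.testing.assert_frame_equal(
        normalize_lanes(equal).sort_index(axis=1),
        equal.sort_index(axis=1), check_like=True)
    single = toy_obs([("A", 2, 100.0, "P1", "9DAF", 1, 1, 50.0)])
    assert normalize_lanes(single)["xic"].iloc[0] == 50.0


def test_normalization_conserves_totals_on_synthetic(small_experiment):
    _, obs, _, _ = small_experiment
    pre_mean = lane_totals(obs).mean()
    post = lane_totals(normalize_lanes(obs))
    assert (post.max() - post.min()) < 1e-6 * pre_mean
    assert post.mean() == pytest.approx(pre_mean)


def test_aggregation_sums_across_slices_and_charges(toy_obs):
    obs = toy_obs([
        ("PEPK", 2, 250.0, "P1", "9DAF", 1, 3, 5.0),
        ("PEPK", 2, 250.0, "P1", "9DAF", 1, 4, 7.0),      # slice neighbour
        ("LONGPEPTIDEK", 2, 700.0, "P2", "9DAF", 1, 5, 5.0),
        ("LONGPEPTIDEK", 3, 467.0, "P2", "9DAF", 1, 5, 7.0),  # other charge
        ("SINGLEK", 2, 400.0, "P3", "13DAF", 2, 8, 3.25),
    ])
    pep = aggregate_peptides(obs)
    lookup = pep.set_index(["peptide_sequence", "stage", "replicate"])
    assert lookup.loc[("PEPK", "9DAF", 1), "abundance"] == 12.0
    assert lookup.loc[("LONGPEPTIDEK", "9DAF", 1), "abundance"] == 12.0
    assert lookup.loc[("SINGLEK", "13DAF", 2), "abundance"] == 3.25
    assert lookup["specific"].all()


def test_aggregation_conserves_lane_totals(small_experiment):
    _, obs, _, _ = small_experiment
    pep = aggregate_peptides(obs)
    agg_totals = pep.groupby(["stage", "replicate"])["abundance"].sum()
    raw_totals = lane_totals(obs)
    pd.testing.assert_series_equal(
        agg_totals.sort_index(), raw_totals.sort_index(),
        check_names=False)


def test_conflicting_attributions_are_dropped(toy_obs):
    obs = toy_obs([
        ("PEPK", 2, 250.0, "P1", "9DAF", 1, 3, 5.0),
        ("PEPK", 2, 250.0, "P2", "9DAF", 1, 4, 7.0),  # same ion, other prot
        ("OTHERK", 2, 300.0, "P1", "9DAF", 1, 3, 2.0),
    ])
    pep = aggregate_peptides(obs)
    assert pep["peptide_sequence"].tolist() == ["OTHERK"]


def test_mz_tolerance_groups_ions(toy_obs):
    mz = 500.0
    within = mz * (1 + 5e-6)    # 5 ppm away: same ion
    beyond = mz * (1 + 5e-5)    # 50 ppm away: different ion
    obs = toy_obs([("PEPK", 2, mz, "P1", "9DAF", 1, 3, 5.0),
                   ("PEPK", 2, within, "P1", "9DAF", 1, 4, 7.0),
                   ("PEPK", 2, beyond, "P1", "9DAF", 1, 5, 100.0)])
    pep = aggregate_peptides(obs)
    # distinct ions of one sequence still merge into one peptide value
    assert len(pep) == 1 and pep["abundance"].iloc[0] == 112.0
    # but grouping kept them separate before the merge (no double count)
    cfg = PipelineConfig(merge_charge_states=False)
    per_charge = aggregate_peptides(obs, cfg)
    assert per_charge["abundance"].iloc[0] == 112.0


def test_filter_peptides_replicate_and_specificity_rules(toy_obs):
    rows = []
    # specific, 1 replicate in each stage -> dropped
    for s in ("9DAF", "13DAF", "19DAF"):
        rows.append(("ONCEK", 2, 300.0, "P1", s, 1, 3, 5.0))
    # specific, 2 replicates of one stage -> kept
    rows += [("TWICEK", 2, 350.0, "P2", "9DAF", 1, 3, 5.0),
             ("TWICEK", 2, 350.0, "P2", "9DAF", 2, 3, 6.0)]
    # shared between two proteins, well replicated -> dropped
    for r in (1, 2, 3):
        rows.append(("SHAREDK", 2, 380.0, "P1;P2", "9DAF", r, 3, 5.0))
    pep = aggregate_peptides(pd.DataFrame(
        rows, columns=["peptide_sequence", "charge", "mz",
                       "protein_accessions", "stage", "replicate", "slice",
                       "xic"]))
    kept = filter_peptides(pep)
    assert set(kept["peptide_sequence"]) == {"TWICEK"}


def test_filter_empty_input():
    empty = aggregate_peptides(pd.DataFrame(
        columns=["peptide_sequence", "charge", "mz", "protein_accessions",
                 "stage", "replicate", "slice", "xic"]))
    assert filter_peptides(empty).empty
    assert quantify_proteins(filter_peptides(empty)).empty


def make_peptides(rows):
    df = pd.DataFrame(rows, columns=["peptide_sequence", "stage",
                                     "replicate", "abundance", "proteins"])
    df["specific"] = ~df["proteins"].str.contains(";")
    return df


def test_protein_summation_and_thresholds():
    rows = []
    # P1: two specific peptides, 3 replicates of 9DAF -> kept, sum 3+4=7
    for r in (1, 2, 3):
        rows += [("A" * 7, "9DAF", r, 3.0, "P1"),
                 ("C" * 7, "9DAF", r, 4.0, "P1")]
    # P2: one specific peptide only -> dropped
    for r in (1, 2, 3):
        rows.append(("D" * 7, "9DAF", r, 9.0, "P2"))
    # P3: two peptides but only 2 replicates in every stage -> dropped
    for s in ("9DAF", "13DAF", "19DAF"):
        for r in (1, 2):
            rows += [("E" * 7, s, r, 1.0, "P3"), ("F" * 7, s, r, 1.0, "P3")]
    prot = quantify_proteins(make_peptides(rows))
    assert set(prot["accession"]) == {"P1"}
    assert (prot["abundance"] == 7.0).all()
    assert (prot["n_specific_peptides"] == 2).all()


def test_filter_monotonicity_in_thresholds(small_experiment):
    """Raising any threshold never enlarges the retained sets."""
    _, obs, _, _ = small_experiment
    norm = normalize_lanes(obs)
    pep = aggregate_peptides(norm)
    base = PipelineConfig()
    peps_base = set(filter_peptides(pep, base)["peptide_sequence"])
    prots_base = set(quantify_proteins(filter_peptides(pep, base),
                                       base)["accession"])
    for kwargs in ({"min_peptide_replicates": 3},
                   {"min_specific_peptides": 4},
                   {"min_replicates_presence": 5}):
        cfg = PipelineConfig(**kwargs)
        peps = set(filter_peptides(pep, cfg)["peptide_sequence"])
        prots = set(quantify_proteins(filter_peptides(pep, cfg),
                                      cfg)["accession"])
        assert peps <= peps_base
        assert prots <= prots_base


def test_noise_free_pipeline_removes_lane_effects_exactly():
    """Pure lane effects (no stage effects, no noise) are removed by
    normalization: every protein is flat across all lanes."""
    cfg = SimulationConfig(n_proteins=25, seed=3, noise_cv=0.0,
                           missing_prob=0.0, lane_effect_sd=0.4,
                           frac_affected=0.0, slice_leak_prob=0.0,
                           shared_peptide_prob=0.0)
    obs, _, _ = simulate_experiment(cfg)
    prot = quantify_proteins(filter_peptides(
        aggregate_peptides(normalize_lanes(obs))))
    for _, grp in prot.groupby("accession"):
        vals = grp["abundance"].to_numpy()
        assert np.ptp(vals) <= 1e-9 * vals.mean()


def test_noise_free_pipeline_recovers_stage_effects():
    """With unit lane effects the stage ratio of an affected protein,
    referenced to any flat protein, equals its configured effect."""
    cfg = SimulationConfig(n_proteins=25, seed=8, noise_cv=0.0,
                           missing_prob=0.0, lane_effect_sd=0.0,
                           frac_affected=0.3, affected_stage=2,
                           slice_leak_prob=0.0, shared_peptide_prob=0.0)
    obs, _, truth = simulate_experiment(cfg)
    prot = quantify_proteins(filter_peptides(
        aggregate_peptides(normalize_lanes(obs))))
    stages = cfg.stage_labels
    means = prot.groupby(["accession", "stage"])["abundance"].mean().unstack()
    ratio = means[stages[2]] / means[stages[0]]
    tp = truth.proteins.set_index("accession")
    flat = tp.index[tp["affected_stage"] == -1]
    affected = tp.index[tp["affected_stage"] == 2]
    assert len(flat) and len(affected)
    # normalization rescales whole lanes, so the double ratio is exact
    for acc in affected:
        rel = ratio[acc] / ratio[flat].mean()
        expected = tp.loc[acc, f"effect_{stages[2]}"]
        assert rel == pytest.approx(expected, rel=1e-6)
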