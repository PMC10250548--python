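import numpy as np
import pytest

from nascentquant.incorporation import (
    NoMatchedPeptidesError,
    estimate_incorporation,
    labeling_efficiency,
    select_matched_peptides,
)
from nascentquant.io_tables import PeptideRecord, peptide_records_from_frame
from nascentquant.simulate import SimulationConfig, simulate_incorporation_dataset

SAMPLES = ["lab_1", "lab_2", "lab_3"]


def rec(seq, mods, intensities, protein="P1"):
    return PeptideRecord(
        sequence=seq,
        charge=2,
        modifications=mods,
        protein_id=protein,
        intensities=dict(zip(SAMPLES, intensities)),
    )


def full_triplet(seq, bes, thr5, thr0):
    """All three modification states of one single-Thr peptide."""
    pos = seq.index("T") + 1
    return [
        rec(seq, [("Thr->bES", pos)], bes),
        rec(seq, [("Thr->Thr5", pos)], thr5),
        rec(seq, [], thr0),
    ]


class TestSelectMatchedPeptides:
    def test_rows_sharing_group_are_summed(self):
        records = [
            rec("ATK", [("Thr->bES", 2)], [3, 10, 20]),
            rec("ATK", [("Thr->bES", 2), ("Acetyl (N-term)", "any")], [7, 10, 20]),
        ]
        mset = select_matched_peptides(records)
        assert mset.groups["bES"].loc["ATK", "lab_1"] == 10  # 3 + 7
        prov = mset.provenance
        assert prov[(prov["sequence"] == "ATK") & (prov["group"] == "bES")][
            "rows_summed"
        ].item() == 2

    def test_multi_threonine_peptides_excluded(self):
        records = [rec("ATTK", [("Thr->bES", 2)], [5, 5, 5])]
        records += full_triplet("ATK", [1, 1, 1], [9, 9, 9], [5, 5, 5])
        mset = select_matched_peptides(records)
        for frame in mset.groups.values():
            assert "ATTK" not in frame.index

    def test_two_replicate_detection_rule(self):
        records = [
            rec("ATK", [("Thr->bES", 2)], [5, None, None]),  # 1 replicate: out
            rec("CTK", [("Thr->bES", 2)], [5, 6, None]),  # 2 replicates: in
        ]
        mset = select_matched_peptides(records)
        assert list(mset.groups["bES"].index) == ["CTK"]

    def test_intersection_counts_peptides_in_all_three_groups(self):
        # 10 peptides: 4 complete triplets, 3 missing the unlabeled form,
        # 3 only unlabeled.
        records = []
        complete = ["ATK", "CTK", "DTK", "ETK"]
        for seq in complete:
            records += full_triplet(seq, [1, 1, 1], [9, 9, 9], [5, 5, 5])
        for seq in ["FTK", "GTK", "HTK"]:
            pos = seq.index("T") + 1
            records.append(rec(seq, [("Thr->bES", pos)], [1, 1, 1]))
            records.append(rec(seq, [("Thr->Thr5", pos)], [9, 9, 9]))
        for seq in ["ITK", "LTK", "MTK"]:
            records.append(rec(seq, [], [5, 5, 5]))
        mset = select_matched_peptides(records)
        assert sorted(mset.intersection) == sorted(complete)

    def test_single_replicate_design_rejected(self):
        record = PeptideRecord("ATK", 2, [], "P1", {"lab_1": 5.0})
        with pytest.raises(ValueError, match="2 replicates"):
            select_matched_peptides([record])


class TestEstimateIncorporation:
    def test_single_peptide_forced_result(self):
        mset = select_matched_peptides(
            full_triplet("ATK", bes=[1, 1, 1], thr5=[39, 39, 39], thr0=[5, 5, 5])
        )
        res = estimate_incorporation(mset, seed=0)
        assert res.substitution_fraction == pytest.approx(0.025)
        assert res.one_in_n == pytest.approx(40.0)
        assert res.n_peptides == 1

    def test_scale_invariance(self):
        records = []
        for seq, b in [("ATK", 1.0), ("CTK", 1.0), ("DTK", 1.0)]:
            records += full_triplet(seq, [b] * 3, [39 * b] * 3, [5 * b] * 3)
        base = estimate_incorporation(select_matched_peptides(records), seed=0)
        scaled_records = []
        for seq, b in [("ATK", 1.0), ("CTK", 1.0), ("DTK", 1.0)]:
            c = 1e6
            scaled_records += full_triplet(
                seq, [b * c] * 3, [39 * b * c] * 3, [5 * b * c] * 3
            )
        scaled = estimate_incorporation(select_matched_peptides(scaled_records), seed=0)
        assert scaled.substitution_fraction == pytest.approx(base.substitution_fraction)
        assert scaled.one_in_n == pytest.approx(40.0)

    def test_group_exchange_symmetry(self):
        records = []
        for seq, r in [("ATK", 0.1), ("CTK", 0.3), ("DTK", 0.05)]:
            records += full_triplet(seq, [r * 100] * 3, [100] * 3, [50] * 3)
        mset = select_matched_peptides(records)
        f = estimate_incorporation(mset, seed=0).substitution_fraction
        # Swap the analog and heavy labels.
        swapped = select_matched_peptides(
            records, bes_mod="Thr->Thr5", thr5_mod="Thr->bES"
        )
        f_swapped = estimate_incorporation(swapped, seed=0).substitution_fraction
        assert f + f_swapped == pytest.approx(1.0)

    def test_empty_intersection_raises_explicitly(self):
        records = [
            rec("ATK", [("Thr->bES", 2)], [1, 1, 1]),
            rec("ATK", [("Thr->Thr5", 2)], [9, 9, 9]),
        ]  # unlabeled form never observed
        with pytest.raises(NoMatchedPeptidesError):
            estimate_incorporation(select_matched_peptides(records))

    @pytest.mark.parametrize("true_p", [0.01, 0.025, 0.1])
    def test_parameter_recovery_without_censoring(self, true_p):
        estimates = []
        for seed in range(20):
            cfg = SimulationConfig(
                n_proteins=150, incorporation_p=true_p, replicate_cv=0.2,
                missing_curve=None, seed=seed,
            )
            table, _ = simulate_incorporation_dataset(cfg)
            mset = select_matched_peptides(peptide_records_from_frame(table))
            estimates.append(
                estimate_incorporation(mset, seed=seed).substitution_fraction
            )
        assert np.mean(estimates) == pytest.approx(true_p, rel=0.10)

    def test_censoring_biases_estimate_downward(self):
        # With left-censoring enabled, low-intensity analog forms drop below
        # the detection curve and are imputed near the censoring floor, so
        # the substitution fraction is systematically underestimated; this
        # documents that direction.
        true_p = 1 / 40.8
        estimates = []
        for seed in range(10):
            cfg = SimulationConfig(
                n_proteins=150, incorporation_p=true_p, replicate_cv=0.2,
                missing_curve=(21.5, 1.0), seed=seed,
            )
            table, _ = simulate_incorporation_dataset(cfg)
            mset = select_matched_peptides(peptide_records_from_frame(table))
            estimates.append(
                estimate_incorporation(mset, seed=seed).substitution_fraction
            )
        mean_f = np.mean(estimates)
        assert mean_f < true_p  # underestimate
        assert mean_f == pytest.approx(true_p, rel=0.5)  # but not wildly off

    def test_mean_ratio_summary_close_to_fraction_summary_at_small_p(self):
        cfg = SimulationConfig(n_proteins=100, replicate_cv=0.1,
                               missing_curve=None, seed=21)
        table, _ = simulate_incorporation_dataset(cfg)
        mset = select_matched_peptides(peptide_records_from_frame(table))
        f1 = estimate_incorporation(mset, seed=0, ratio_summary="fraction")
        f2 = estimate_incorporation(mset, seed=0, ratio_summary="mean_ratio")
        assert f1.one_in_n == pytest.approx(f2.one_in_n, rel=0.02)


class TestLabelingEfficiency:
    @pytest.mark.parametrize(
        "n_mod,n_total,expected", [(142, 10_000, 1.4), (0, 10, 0.0), (7, 200, 3.5)]
    )
    def test_percentage_to_one_decimal(self, n_mod, n_total, expected):
        assert labeling_efficiency(n_mod, n_total) == expected

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            labeling_efficiency(1, 0)
        with pytest.raises(ValueError):
            labeling_efficiency(5, 3)
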