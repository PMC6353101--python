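"""Decoder: export parsing, well gating, replicate aggregation, blinded scoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fishid import paperdata
from fishid.decoder import (
    MULTIPLE_CALL,
    NONE_CALL,
    DecoderConfig,
    QPCRParseError,
    QPCRWellRecord,
    call_well,
    decode_run,
    decode_sample,
    evaluate_blinded,
    parse_qpcr_export,
)
from fishid.simulate import generate_qpcr_run


def well(cq, status=True, drn=0.6, sample="S1", target="Lake Whitefish", name="A1"):
    return QPCRWellRecord(
        well=name, sample_id=sample, target_species=target, dye="FAM",
        cq=cq, amp_status=status, delta_rn=drn,
    )


class TestParseExport:
    def test_typical_row(self, tmp_path):
        path = tmp_path / "run.csv"
        path.write_text(
            "Well,Sample,Target,Dye,Cq,Amp Status,Delta Rn\n"
            "A1,S1,Lake Whitefish,FAM,16.21,Amp,1.2\n"
        )
        (rec,) = parse_qpcr_export(path)
        assert rec.cq == 16.21
        assert rec.amp_status is True
        assert rec.delta_rn == 1.2
        assert rec.target_species == "Lake Whitefish"

    def test_undetermined_is_missing_not_zero(self, tmp_path):
        path = tmp_path / "run.csv"
        path.write_text(
            "Well,Sample,Target,Cq,Amp Status,Delta Rn\n"
            "A1,S1,Lake Whitefish,Undetermined,No Amp,0.01\n"
        )
        (rec,) = parse_qpcr_export(path)
        assert rec.cq is None
        assert rec.amp_status is False

    def test_missing_column_names_schema(self, tmp_path):
        path = tmp_path / "run.csv"
        path.write_text("Well,Sample,Target,Cq\nA1,S1,x,12\n")
        with pytest.raises(QPCRParseError, match="columns found"):
            parse_qpcr_export(path)

    def test_roundtrip_through_simulator(self, tmp_path):
        run = generate_qpcr_run(paperdata.blinded_run_spec(seed=3))
        path = tmp_path / "run.csv"
        run.to_csv(path)
        records = parse_qpcr_export(path)
        assert len(records) == len(run.wells)
        for rec, (_, row) in zip(records, run.wells.iterrows()):
            assert rec.sample_id == row["Sample"]
            assert rec.target_species == row["Target"]
            if row["Cq"] == "Undetermined":
                assert rec.cq is None
            else:
                assert rec.cq == pytest.approx(float(row["Cq"]))


class TestCallWell:
    @pytest.mark.parametrize(
        "cq,status,drn,expected",
        [
            (23.79, True, 0.6, True),   # target-level Cq passes all gates
            (37.66, True, 0.6, False),  # cross-reaction Cq far above cutoff
            (None, True, 0.6, False),   # Undetermined never calls
            (28.71, True, 0.6, False),  # mixed-template smallmouth, above 25
            (24.0, False, 0.6, False),  # amplification status gate
            (24.0, True, 0.2, False),   # deltaRn gate
            (25.0, True, 0.3, True),    # both thresholds inclusive
        ],
    )
    def test_three_gates(self, cq, status, drn, expected):
        assert call_well(well(cq, status, drn)) is expected

    def test_mixed_mode_uses_adjusted_cutoff(self):
        config = DecoderConfig(mixed_sample_mode=True, mixed_cq_cutoff=30.0)
        assert call_well(well(28.71), config) is True
        assert call_well(well(28.71)) is False

    @settings(max_examples=40, derandomize=True)
    @given(
        st.floats(1.0, 39.9),
        st.floats(1.0, 39.0),
        st.floats(0.1, 38.0),
    )
    def test_monotone_in_cq_cutoff(self, cq, cutoff_lo, delta):
        cutoff_hi = min(cutoff_lo + delta, 39.9)
        rec = well(cq)
        lo = call_well(rec, DecoderConfig(cq_cutoff=cutoff_lo))
        hi = call_well(rec, DecoderConfig(cq_cutoff=cutoff_hi))
        assert hi or not lo  # raising the cutoff never loses a positive


class TestDecodeSample:
    def test_duplicate_wells_mean_identifies_species(self):
        records = [
            well(16.1, name="A1"),
            well(16.3, name="A2"),
            well(None, status=False, drn=0.05, target="Yellow Perch", name="A3"),
            well(None, status=False, drn=0.05, target="Yellow Perch", name="A4"),
        ]
        call = decode_sample(records)
        assert call.identified_species == "Lake Whitefish"
        lw = dict((sp, (cq, pos)) for sp, cq, pos in call.calls)["Lake Whitefish"]
        assert lw[0] == pytest.approx(16.2)

    def test_all_undetermined_is_none(self):
        records = [well(None, status=False, drn=0.05, name=f"A{i}") for i in range(4)]
        assert decode_sample(records).identified_species == NONE_CALL

    def test_two_positive_species_is_multiple(self):
        records = [
            well(16.0, name="A1"),
            well(18.0, target="Rainbow Smelt", name="A2"),
        ]
        call = decode_sample(records)
        assert call.identified_species == MULTIPLE_CALL
        assert set(call.positive_species) == {"Lake Whitefish", "Rainbow Smelt"}

    def test_permutation_invariant(self):
        records = [
            well(16.1, name="A1"),
            well(16.3, name="A2"),
            well(36.0, target="Smallmouth Bass", name="A3"),
            well(None, status=False, drn=0.05, target="Smallmouth Bass", name="A4"),
        ]
        forward = decode_sample(records)
        backward = decode_sample(list(reversed(records)))
        assert forward.identified_species == backward.identified_species
        assert forward.calls == backward.calls

    def test_mean_rule_gates_before_averaging(self):
        # a failing-status well must not drag the mean
        records = [well(16.0, name="A1"), well(39.0, status=False, name="A2")]
        call = decode_sample(records)
        assert call.identified_species == "Lake Whitefish"

    def test_empty_and_mixed_sample_ids_rejected(self):
        with pytest.raises(ValueError):
            decode_sample([])
        with pytest.raises(ValueError):
            decode_sample([well(16.0), well(16.0, sample="S2", name="B1")])


class TestEvaluateBlinded:
    def small_run(self, seed=7, corrupt=None):
        """3 target samples + 1 control sample, decoded from simulated wells."""
        from fishid.simulate import CqStat, RunSpec

        stats = {
            ("Lake Whitefish", "Lake Whitefish"): CqStat(16.21, 0.35),
            ("Lake Whitefish", "Rainbow Smelt"): CqStat(None),
            ("Rainbow Smelt", "Rainbow Smelt"): CqStat(18.83, 0.38),
            ("Rainbow Smelt", "Lake Whitefish"): CqStat(None),
            ("Cisco", "Lake Whitefish"): CqStat(None),
            ("Cisco", "Rainbow Smelt"): CqStat(None),
        }
        design = [
            ("s1", "Lake Whitefish", 2),
            ("s2", "Lake Whitefish", 2),
            ("s3", "Rainbow Smelt", 2),
            ("s4", "Cisco", 2),
        ]
        assays_for = {s: ["Lake Whitefish", "Rainbow Smelt"] for s, _, _ in design}
        run = generate_qpcr_run(
            RunSpec(seed=seed, design=design, assays_for=assays_for, stats=stats)
        )
        records = []
        for _, row in run.wells.iterrows():
            cq = None if row["Cq"] == "Undetermined" else float(row["Cq"])
            if corrupt and row["Sample"] == corrupt and cq is not None:
                cq = 39.0
            records.append(
                QPCRWellRecord(
                    well=row["Well"], sample_id=row["Sample"],
                    target_species=row["Target"], dye=row["Dye"], cq=cq,
                    amp_status=row["Amp Status"] == "Amp",
                    delta_rn=float(row["Delta Rn"]),
                )
            )
        return decode_run(records), run.truth

    def test_clean_run_scores_perfectly(self):
        calls, truth = self.small_run()
        metrics = evaluate_blinded(calls, truth)
        assert metrics.accuracy_percent == 100.0
        assert metrics.false_positive_count == 0
        assert metrics.n_target_samples == 3
        assert metrics.n_nontarget_samples == 1

    def test_corrupting_one_target_drops_accuracy_by_one_nth(self):
        calls, truth = self.small_run(corrupt="s2")
        metrics = evaluate_blinded(calls, truth)
        assert metrics.accuracy_percent == pytest.approx(100.0 * 2 / 3)

    def test_no_target_samples_reports_not_applicable(self):
        calls, truth = self.small_run()
        only_con = [c for c in calls if truth[c.sample_id] == "Cisco"]
        metrics = evaluate_blinded(only_con, truth)
        assert metrics.accuracy_percent is None
        assert metrics.n_target_samples == 0

    def test_missing_truth_rejected(self):
        calls, truth = self.small_run()
        truth = {k: v for k, v in truth.items() if k != "s1"}
        with pytest.raises(ValueError, match="missing from truth"):
            evaluate_blinded(calls, truth)


class TestMultiplexStats:
    def test_mixed_template_diagonal_calls(self):
        """With mixed-template Cq statistics, smallmouth bass and round
        whitefish sit above the default cutoff and need the adjusted one."""
        stats = paperdata.load_cq_stats("multiplex")
        default, mixed = DecoderConfig(), DecoderConfig(mixed_sample_mode=True)
        for species, expect_default in [
            ("Smallmouth Bass", False),   # 28.71
            ("Round Whitefish", False),   # 25.23
            ("Spottail Shiner", True),    # 21.37
            ("Brook Trout", True),        # 23.44
        ]:
            stat = stats[(species, species)]
            rec = well(stat.mean_cq, target=species)
            assert call_well(rec, default) is expect_default, species
            assert call_well(rec, mixed) is True, species
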