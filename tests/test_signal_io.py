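"""Trial file round trips, parse errors, and validation findings."""

import dataclasses

import numpy as np
import pytest

from sptphase import (SyntheticSpec, TrialParseError, generate_trial,
                      read_trial, validate_trial, write_trial)

HEADER = """\
# trial_id: demo
# fs_force: 600
# fs_kin: 60
# force_units: N
# length_units: m
"""


def small_trial_text(n_force=40, n_kin=4, force_units="N", length_units="m",
                     fs_kin=60, kin_rows=None):
    lines = [f"# trial_id: demo", f"# fs_force: 600", f"# fs_kin: {fs_kin}",
             f"# force_units: {force_units}", f"# length_units: {length_units}",
             "time,f_trailing_hand,f_initial_seat,f_target_seat"]
    for i in range(n_force):
        t = i / 600
        lines.append(f"{t:.6f},1.0,700.0,0.0")
    lines.append("")
    lines.append("time,c7_x,c7_y,c7_z")
    if kin_rows is None:
        kin_rows = [f"{i / fs_kin:.6f},0.1,0.2,0.3" for i in range(n_kin)]
    lines.extend(kin_rows)
    return "\n".join(lines) + "\n"


class TestRoundTrip:
    def test_synthetic_trial_write_read_round_trip(self, tmp_path):
        raw, _ = generate_trial(SyntheticSpec(seed=21, trial_id="rt"))
        p = tmp_path / "rt.csv"
        write_trial(raw, p)
        back = read_trial(p)
        assert back.trial_id == raw.trial_id
        assert back.fs_force == raw.fs_force and back.fs_kin == raw.fs_kin
        # equality to the declared (6-decimal) write precision
        for name in ("force_time", "f_trailing_hand", "f_initial_seat",
                     "f_target_seat", "kin_time"):
            np.testing.assert_allclose(getattr(back, name),
                                       getattr(raw, name), atol=5e-7)
        np.testing.assert_allclose(back.c7_xyz, raw.c7_xyz, atol=5e-7)

    def test_declared_duration_matches_frame_counts(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(small_trial_text(n_force=1200, n_kin=120))
        raw = read_trial(p)
        assert raw.n_force == 1200 and raw.n_kin == 120
        assert raw.duration_s == pytest.approx(2.0)


class TestParseErrors:
    def test_missing_header_key(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(small_trial_text().replace("# fs_kin: 60\n", ""))
        with pytest.raises(TrialParseError, match="fs_kin"):
            read_trial(p)

    def test_non_numeric_cell_names_line(self, tmp_path):
        text = small_trial_text().replace("0.001667,1.0,700.0,0.0",
                                          "0.001667,oops,700.0,0.0")
        p = tmp_path / "t.csv"
        p.write_text(text)
        with pytest.raises(TrialParseError, match=r"line 8.*oops"):
            read_trial(p)

    def test_ragged_force_row_rejected_with_line_number(self, tmp_path):
        text = small_trial_text().replace("0.005000,1.0,700.0,0.0",
                                          "0.005000,1.0,700.0")
        p = tmp_path / "t.csv"
        p.write_text(text)
        with pytest.raises(TrialParseError, match="line 10"):
            read_trial(p)

    def test_unknown_units_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(small_trial_text(force_units="dyn"))
        with pytest.raises(TrialParseError, match="force_units"):
            read_trial(p)

    def test_unit_conversion_to_si(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(small_trial_text(force_units="kN", length_units="mm"))
        raw = read_trial(p)
        assert raw.f_initial_seat[0] == pytest.approx(700e3)
        assert raw.c7_xyz[0, 0] == pytest.approx(0.1e-3)


class TestOcclusions:
    def test_short_occlusion_interpolated_with_warning(self, tmp_path):
        rows = [f"{i / 60:.6f},{0.1 + 0.01 * i:.4f},0.2,0.3" for i in range(6)]
        rows[2] = f"{2 / 60:.6f},,,"
        p = tmp_path / "t.csv"
        p.write_text(small_trial_text(kin_rows=rows))
        with pytest.warns(UserWarning, match="occluded"):
            raw = read_trial(p)
        assert raw.occluded_frames.tolist() == [2]
        assert raw.c7_xyz[2, 0] == pytest.approx(0.12)  # linear fill

    def test_long_occlusion_run_is_an_error(self, tmp_path):
        rows = [f"{i / 60:.6f},0.1,0.2,0.3" for i in range(8)]
        for i in (2, 3, 4, 5):
            rows[i] = f"{i / 60:.6f},,,"
        p = tmp_path / "t.csv"
        p.write_text(small_trial_text(kin_rows=rows))
        with pytest.raises(TrialParseError, match="occlusion run"):
            read_trial(p)


class TestValidateTrial:
    def test_clean_synthetic_trial_has_empty_report(self, noiseless_trial):
        raw, _ = noiseless_trial
        report = validate_trial(raw)
        assert report.ok and not report.issues

    def test_validate_does_not_mutate_input(self, noisy_trial):
        raw, _ = noisy_trial
        before = raw.f_trailing_hand.copy()
        validate_trial(raw)
        np.testing.assert_array_equal(raw.f_trailing_hand, before)

    def test_non_integer_decimation_factor_is_an_error(self, noiseless_trial):
        raw, _ = noiseless_trial
        bad = dataclasses.replace(raw, fs_kin=64.0)
        report = validate_trial(bad)
        assert any("non-integer decimation factor" in m for m in report.errors)

    def test_all_zero_target_seat_warns(self, noiseless_trial):
        raw, _ = noiseless_trial
        bad = dataclasses.replace(raw,
                                  f_target_seat=np.zeros_like(raw.f_target_seat))
        report = validate_trial(bad)
        assert report.ok  # processable, but...
        assert any("identically zero" in m for m in report.warnings)

    def test_large_negative_forces_warn(self, noiseless_trial):
        raw, _ = noiseless_trial
        bad = dataclasses.replace(raw,
                                  f_trailing_hand=raw.f_trailing_hand - 50.0)
        report = validate_trial(bad)
        assert any("positive upward" in m for m in report.warnings)

    def test_short_trial_warns(self):
        spec = SyntheticSpec(baseline_s=0.35, tail_s=0.2, seed=0,
                             true_durations_s=(0.2, 0.2, 0.2, 0.2))
        raw, _ = generate_trial(spec)
        report = validate_trial(raw)
        assert any("shorter than 2 s" in m for m in report.warnings)

    def test_mismatched_channel_length_is_an_error(self, noiseless_trial):
        raw, _ = noiseless_trial
        bad = dataclasses.replace(raw,
                                  f_initial_seat=raw.f_initial_seat[:-5])
        report = validate_trial(bad)
        assert any("length differs" in m for m in report.errors)
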