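"""Batch pipeline, ID-per-cell normalization and group statistics."""

import math
from dataclasses import replace

import numpy as np
import pytest
import scipy.stats

from conftest import make_record
from sabgal.batch import (
    compare_groups,
    id_per_cell,
    nucleus_area_summary,
    process_batch,
    significance_stars,
)
from sabgal.io import pair_images, write_records_csv
from sabgal.signal import ColorThreshold, SignalMeasurement
from sabgal.synthetic import SyntheticSpec, generate_experiment, two_group_preset

PIPE_THR = ColorThreshold(0, 230, 0, 235, 0, 255)


def pooled_t_oracle(a, b):
    """Closed-form pooled-variance two-sample t and two-sided p."""
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    t = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    p = 2 * scipy.stats.t.cdf(-abs(t), df)
    return t, df, p


class TestIdPerCell:
    def test_division(self):
        sig = SignalMeasurement(10, 1000.0, 100.0)
        assert id_per_cell(sig, 4) == 250.0

    def test_zero_signal(self):
        assert id_per_cell(SignalMeasurement(0, 0.0, 0.0), 7) == 0.0

    def test_zero_nuclei_is_error_not_zero(self):
        with pytest.raises(ZeroDivisionError):
            id_per_cell(SignalMeasurement(5, 500.0, 100.0), 0)

    def test_cells_per_nucleus_correction(self):
        sig = SignalMeasurement(10, 1000.0, 100.0)
        # multinucleated culture: 2 nuclei per cell -> half as many cells
        assert id_per_cell(sig, 4, cells_per_nucleus=0.5) == 500.0


class TestCompareGroups:
    def _records(self, a_vals, b_vals, **kw):
        recs = [
            make_record(f"a_{i}", "A", v * 4, 4, **kw) for i, v in enumerate(a_vals)
        ]
        recs += [
            make_record(f"b_{i}", "B", v * 4, 4, **kw) for i, v in enumerate(b_vals)
        ]
        return recs

    def test_identical_groups(self):
        gs = compare_groups(self._records([1, 2, 3], [1, 2, 3]), "A", "B")
        assert gs.t_statistic == pytest.approx(0.0)
        assert gs.p_value == pytest.approx(1.0)
        assert gs.stars == "ns"

    def test_closed_form_oracle(self):
        gs = compare_groups(self._records([1, 2, 3], [4, 5, 6]), "A", "B")
        t, df, p = pooled_t_oracle([1, 2, 3], [4, 5, 6])
        assert gs.t_statistic == pytest.approx(t, abs=5e-4)
        assert gs.t_statistic == pytest.approx(-3.674, abs=5e-4)
        assert gs.df == df == 4
        assert gs.p_value == pytest.approx(p, abs=1e-6)
        assert gs.p_value == pytest.approx(0.0213, abs=5e-4)
        assert gs.stars == "*"

    def test_zero_variance_error(self):
        with pytest.raises(ValueError, match="variance"):
            compare_groups(self._records([5, 5], [5, 5]), "A", "B")

    def test_too_few_records_error(self):
        with pytest.raises(ValueError, match=">= 2"):
            compare_groups(self._records([1], [2, 3]), "A", "B")

    def test_antisymmetric_under_group_swap(self):
        recs = self._records([1.0, 2.5, 3.1], [4.2, 5.0, 6.9])
        ab = compare_groups(recs, "A", "B")
        ba = compare_groups(recs, "B", "A")
        assert ab.t_statistic == pytest.approx(-ba.t_statistic)
        assert ab.p_value == pytest.approx(ba.p_value)

    def test_rejected_records_never_contribute(self):
        recs = self._records([1, 2, 3], [4, 5, 6])
        recs.append(make_record("a_out", "A", 1e9, 4, qc_status="rejected"))
        gs = compare_groups(recs, "A", "B")
        assert gs.n_a == 3 and gs.mean_a == pytest.approx(2.0)

    def test_welch_flag(self):
        recs = self._records([1.0, 2.0, 3.0, 2.5], [4.0, 8.0, 16.0])
        student = compare_groups(recs, "A", "B")
        welch = compare_groups(recs, "A", "B", welch=True)
        assert welch.df != student.df  # Welch df is non-integer here

    def test_per_replicate_aggregation(self):
        recs = self._records([1, 3], [10, 12], replicate="r1")
        recs += self._records([5, 7], [20, 22], replicate="r2")
        # fix ids to be unique
        for i, r in enumerate(recs):
            r.field_id = f"f{i}"
        gs = compare_groups(recs, "A", "B", per_replicate=True)
        assert gs.n_a == gs.n_b == 2
        assert gs.mean_a == pytest.approx((2 + 6) / 2)

    def test_star_thresholds(self):
        assert significance_stars(0.2) == "ns"
        assert significance_stars(0.05) == "*"
        assert significance_stars(0.01) == "**"
        assert significance_stars(0.001) == "***"


class TestNucleusAreaSummary:
    def test_field_and_group_means(self):
        recs = [
            make_record("a", "ctl", 100, 2, mean_nucleus_area=200.0),
            make_record("b", "ctl", 100, 2, mean_nucleus_area=400.0),
        ]
        out = nucleus_area_summary(recs)
        assert out.loc["ctl", "mean"] == pytest.approx(300.0)
        assert out.loc["ctl", "n_fields"] == 2

    def test_nucleus_size_difference_recovered_end_to_end(self, tmp_path):
        """Groups generated with nucleus radius 12 vs 18 px: segmented mean
        areas recover pi*r^2 within 5% and the t test separates them."""
        base = SyntheticSpec(
            image_size=(384, 384),
            n_cells=6,
            cell_radius_px=(21.0, 26.0),
            stain_intensity=(0.5, 0.05),
        )
        specs = {
            "small": replace(base, nucleus_radius_px=(12.0, 12.0)),
            "large": replace(base, nucleus_radius_px=(18.0, 18.0)),
        }
        generate_experiment(specs, fields_per_group=5, out_dir=tmp_path, seed=7)
        pairs, _ = pair_images(tmp_path)
        records, _ = process_batch(pairs, PIPE_THR)
        summary = nucleus_area_summary(records)
        for group, r in (("small", 12.0), ("large", 18.0)):
            assert summary.loc[group, "mean"] == pytest.approx(
                math.pi * r**2, rel=0.05
            )
        gs = compare_groups(records, "small", "large", "mean_nucleus_area")
        assert gs.p_value <= 0.05


class TestProcessBatch:
    @pytest.fixture
    def experiment_dir(self, tmp_path):
        specs = two_group_preset()
        generate_experiment(
            {"control": specs["control"], "senescent": specs["senescent"]},
            fields_per_group=2,
            out_dir=tmp_path,
            seed=11,
        )
        return tmp_path

    def test_non_interactive_marks_auto(self, experiment_dir):
        pairs, _ = pair_images(experiment_dir)
        records, _ = process_batch(pairs, PIPE_THR)
        assert len(records) == 4
        assert all(r.qc_status == "auto" for r in records)
        assert all(r.id_per_cell is not None for r in records)

    def test_zero_nuclei_field_rejected_batch_continues(self, experiment_dir):
        import imageio.v3 as iio

        blank = np.zeros((64, 64), dtype=np.uint8)
        iio.imwrite(experiment_dir / "empty_0_BF.tif", np.full((64, 64, 3), 255, np.uint8))
        iio.imwrite(experiment_dir / "empty_0_DAPI.tif", blank)
        pairs, _ = pair_images(experiment_dir)
        records, _ = process_batch(pairs, PIPE_THR)
        by_id = {r.field_id: r for r in records}
        assert by_id["empty_0"].qc_status == "rejected"
        assert by_id["empty_0"].reason == "zero nuclei"
        assert sum(r.accepted for r in records) == 4

    def test_order_invariance(self, experiment_dir):
        pairs, _ = pair_images(experiment_dir)
        fwd, _ = process_batch(pairs, PIPE_THR)
        rev, _ = process_batch(list(reversed(pairs)), PIPE_THR)
        assert [(r.field_id, r.id_per_cell) for r in fwd] == [
            (r.field_id, r.id_per_cell) for r in rev
        ]

    def test_determinism_byte_identical_csv(self, experiment_dir, tmp_path):
        pairs, _ = pair_images(experiment_dir)
        out1, out2 = tmp_path / "r1.csv", tmp_path / "r2.csv"
        for out in (out1, out2):
            records, _ = process_batch(pairs, PIPE_THR)
            write_records_csv(records, out)
        assert out1.read_bytes() == out2.read_bytes()

    def test_interactive_prompt_recorded(self, experiment_dir, tmp_path):
        pairs, _ = pair_images(experiment_dir)
        answers = iter(["y", "n", "y", "y"])
        records, _ = process_batch(
            pairs,
            PIPE_THR,
            interactive=True,
            out_dir=tmp_path / "qc",
            confirm=lambda _msg: next(answers),
        )
        statuses = [r.qc_status for r in records]
        assert statuses.count("accepted") == 3 and statuses.count("rejected") == 1
        log = (tmp_path / "qc" / "qc_log.txt").read_text()
        assert "operator rejected" in log
        overlays = list((tmp_path / "qc").glob("*_overlay.png"))
        assert len(overlays) == 4

    def test_empty_batch_error(self):
        with pytest.raises(ValueError):
            process_batch([], PIPE_THR)
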