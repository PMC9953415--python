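"""Supervised batch pipeline and group statistics.

Runs the two-module measurement over an image catalogue — colour-threshold
integrated density on each brightfield image, nuclei count on its DAPI
partner — and reduces each field of view to an ID-per-cell value, the
final quantity carried into statistics.  Group comparisons use the
two-tailed equal-variance Student's t test with significance stars at
p <= 0.05 / 0.01 / 0.001; data are summarised as mean +/- SD (SEM is also
reported for figure captions).

Supervision is headless: QC overlays are written per field and, in
interactive mode, the operator accepts or rejects each field at a terminal
prompt; decisions land in an audit log.  Rejected fields never contribute
to statistics.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import ImagePair, read_image, write_image, write_records_csv
from .nuclei import NucleiParams, NucleiResult, segment_nuclei
from .signal import (
    ColorThreshold,
    SignalMeasurement,
    apply_color_threshold,
    measure_signal,
    render_overlay,
)

__all__ = [
    "FieldRecord",
    "GroupStats",
    "id_per_cell",
    "process_batch",
    "compare_groups",
    "nucleus_area_summary",
]

STAR_CUTOFFS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for cutoff, stars in STAR_CUTOFFS:
        if p <= cutoff:
            return stars
    return "ns"


@dataclass
class FieldRecord:
    """Measurement record for one field of view.

    ``id_per_cell`` is defined only for fields with at least one nucleus;
    fields rejected during QC (or failing to process) are excluded from all
    statistics.  ``qc_status`` is "accepted"/"rejected" in interactive mode
    and "auto" otherwise; ``replicate`` optionally tags the biological
    repeat for per-replicate aggregation.
    """

    field_id: str
    group: str
    signal: SignalMeasurement | None = None
    nuclei_count: int | None = None
    id_per_cell: float | None = None
    qc_status: str = "auto"
    reason: str = ""
    mean_nucleus_area: float | None = None
    replicate: str | None = None

    @property
    def accepted(self) -> bool:
        return self.qc_status in ("accepted", "auto")


@dataclass(frozen=True)
class GroupStats:
    """Two-group comparison: mean +/- SD per group and the t test."""

    group_a: str
    group_b: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t_statistic: float
    df: float
    p_value: float
    stars: str

    @property
    def sem_a(self) -> float:
        return self.sd_a / math.sqrt(self.n_a)

    @property
    def sem_b(self) -> float:
        return self.sd_b / math.sqrt(self.n_b)

    def summary(self) -> str:
        return (
            f"{self.group_a}: {self.mean_a:g} ± {self.sd_a:g} (SD), n={self.n_a}\n"
            f"{self.group_b}: {self.mean_b:g} ± {self.sd_b:g} (SD), n={self.n_b}\n"
            f"t = {self.t_statistic:.4f}, df = {self.df:g}, "
            f"p = {self.p_value:.4g} [{self.stars}]"
        )


def id_per_cell(
    signal: SignalMeasurement, nuclei_count: int, cells_per_nucleus: float = 1.0
) -> float:
    """Integrated density divided by estimated cell number.

    The cell number is ``nuclei_count * cells_per_nucleus``; the correction
    factor (< 1 in multinucleated cultures) defaults to 1.  A field with no
    nuclei has no defined value and must be rejected, never zeroed.
    """
    if nuclei_count < 0:
        raise ValueError("nuclei_count must be non-negative")
    if nuclei_count == 0:
        raise ZeroDivisionError(
            "id_per_cell undefined for a field with zero nuclei; reject the field"
        )
    return signal.integrated_density / (nuclei_count * cells_per_nucleus)


def _utc_now() -> str:
    return _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")


def process_batch(
    pairs: Sequence[ImagePair],
    thr: ColorThreshold,
    nuc: NucleiParams | None = None,
    interactive: bool = False,
    out_dir: str | Path | None = None,
    cells_per_nucleus: float = 1.0,
    luminance: bool = False,
    confirm: Callable[[str], str] = input,
) -> tuple[list[FieldRecord], dict[str, NucleiResult]]:
    """Measure every field in a catalogue under one calibrated threshold.

    Fields are processed in lexicographic field-id order, so the output is
    independent of the order in which pairs are supplied.  Per-field
    failures (unreadable images, zero nuclei) reject that field with a
    reason and the batch continues.  When ``out_dir`` is given, a QC
    overlay PNG and nuclei label map are written per field together with a
    ``qc_log.txt`` audit trail.  In interactive mode each field must be
    confirmed (``y``/``n``) via ``confirm`` (the terminal by default).

    Returns the records plus the per-field nuclei segmentations (for
    nucleus-area analyses).
    """
    if not pairs:
        raise ValueError("empty batch")
    if nuc is None:
        nuc = NucleiParams()
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
    records: list[FieldRecord] = []
    nuclei_results: dict[str, NucleiResult] = {}
    log_lines: list[str] = []
    for pair in sorted(pairs, key=lambda p: p.field_id):
        rec = FieldRecord(field_id=pair.field_id, group=pair.group)
        try:
            bf = read_image(pair.bf_path)
            dapi_rgb = read_image(pair.dapi_path)
            dapi = dapi_rgb.astype(np.float64).mean(axis=2)
            mask = apply_color_threshold(bf, thr)
            rec.signal = measure_signal(bf, mask, luminance=luminance)
            seg = segment_nuclei(dapi, nuc)
            nuclei_results[pair.field_id] = seg
            rec.nuclei_count = seg.count
            if seg.count > 0:
                rec.mean_nucleus_area = float(seg.areas.mean())
            if out_dir is not None:
                write_image(
                    out_dir / f"{pair.field_id}_overlay.png", render_overlay(bf, mask)
                )
                write_image(
                    out_dir / f"{pair.field_id}_labels.tif",
                    seg.label_map.astype(np.uint16),
                )
            rec.id_per_cell = id_per_cell(rec.signal, seg.count, cells_per_nucleus)
        except ZeroDivisionError:
            rec.qc_status, rec.reason = "rejected", "zero nuclei"
        except (OSError, ValueError) as exc:
            rec.qc_status, rec.reason = "rejected", str(exc)
        else:
            if interactive:
                answer = confirm(
                    f"{pair.field_id}: area={rec.signal.area_px} "
                    f"ID={rec.signal.integrated_density:.1f} "
                    f"nuclei={rec.nuclei_count} — accept? [y/n] "
                )
                if answer.strip().lower().startswith("y"):
                    rec.qc_status = "accepted"
                else:
                    rec.qc_status, rec.reason = "rejected", "operator rejected"
            else:
                rec.qc_status = "auto"
        records.append(rec)
        log_lines.append(
            f"{rec.field_id}\t{rec.qc_status}\t{rec.reason}\t{_utc_now()}"
        )
    if out_dir is not None:
        (out_dir / "qc_log.txt").write_text("\n".join(log_lines) + "\n")
    return records, nuclei_results


def _accepted_values(
    records: Iterable[FieldRecord], group: str, value_field: str, per_replicate: bool
) -> np.ndarray:
    vals: list[tuple[str | None, float]] = []
    for rec in records:
        if rec.group != group or not rec.accepted:
            continue
        v = getattr(rec, value_field) if value_field != "area_px" else (
            rec.signal.area_px if rec.signal is not None else None
        )
        if v is None:
            continue
        vals.append((rec.replicate, float(v)))
    if per_replicate:
        if any(r is None for r, _ in vals):
            raise ValueError(
                f"group {group!r}: per-replicate aggregation requires every "
                "record to carry a replicate label"
            )
        df = pd.DataFrame(vals, columns=["replicate", "value"])
        return df.groupby("replicate")["value"].mean().to_numpy()
    return np.array([v for _, v in vals])


def compare_groups(
    records: Iterable[FieldRecord],
    group_a: str,
    group_b: str,
    value_field: str = "id_per_cell",
    welch: bool = False,
    per_replicate: bool = False,
) -> GroupStats:
    """Two-tailed Student's t test between two groups of accepted fields.

    ``value_field`` is one of ``id_per_cell``, ``area_px`` or
    ``mean_nucleus_area``.  The default test pools variance (classic
    Student's); Welch's correction is available via ``welch=True``.  SDs
    use the n-1 denominator.  With ``per_replicate=True`` field values are
    first averaged within each biological replicate and the test runs on
    replicate means.
    """
    if value_field not in ("id_per_cell", "area_px", "mean_nucleus_area"):
        raise ValueError(f"unknown value_field {value_field!r}")
    records = list(records)
    a = _accepted_values(records, group_a, value_field, per_replicate)
    b = _accepted_values(records, group_b, value_field, per_replicate)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"need >= 2 accepted values per group, got {len(a)} ({group_a!r}) "
            f"and {len(b)} ({group_b!r})"
        )
    sd_a = float(np.std(a, ddof=1))
    sd_b = float(np.std(b, ddof=1))
    pooled_var = ((len(a) - 1) * sd_a**2 + (len(b) - 1) * sd_b**2) / (
        len(a) + len(b) - 2
    )
    if pooled_var == 0:
        raise ValueError("zero pooled variance: t statistic undefined")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    df = float(res.df) if hasattr(res, "df") else float(len(a) + len(b) - 2)
    p = float(res.pvalue)
    return GroupStats(
        group_a=group_a,
        group_b=group_b,
        mean_a=float(a.mean()),
        sd_a=sd_a,
        n_a=len(a),
        mean_b=float(b.mean()),
        sd_b=sd_b,
        n_b=len(b),
        t_statistic=float(res.statistic),
        df=df,
        p_value=p,
        stars=significance_stars(p),
    )


def nucleus_area_summary(records: Iterable[FieldRecord]) -> pd.DataFrame:
    """Per-group mean +/- SD of the per-field mean nucleus area.

    Nuclear enlargement accompanies senescence, so the per-field mean
    nucleus area is a useful secondary readout; feed ``compare_groups``
    with ``value_field="mean_nucleus_area"`` for the formal test.
    """
    rows = [
        {"group": r.group, "mean_nucleus_area": r.mean_nucleus_area}
        for r in records
        if r.accepted and r.mean_nucleus_area is not None
    ]
    if not rows:
        raise ValueError("no accepted fields with nuclei")
    df = pd.DataFrame(rows)
    out = df.groupby("group")["mean_nucleus_area"].agg(["mean", "std", "count"])
    return out.rename(columns={"count": "n_fields"})


def save_batch(records: Sequence[FieldRecord], path: str | Path) -> None:
    """Write the batch records CSV (8-column schema in :mod:`sabgal.io`)."""
    write_records_csv(records, path)
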