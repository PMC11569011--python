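"""Estimator-vs-reference comparison.

Comparisons run on one-second window averages of the aligned series
(sample-wise comparison is available via ``window_s=None``), mirroring
how wearable posture angles are typically reported.  RMSE is broken down
by activity label, with an "all_activities" pool over the union of
labeled windows — never the mean of the per-activity RMSEs.  The MAD
histogram bins the mean absolute estimator-reference difference by the
reference angle rounded to the nearest whole degree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from camptokin.io_formats import ActivitySegments

OVERALL_LABEL = "all_activities"


@dataclass
class EvaluationReport:
    """Per-activity and overall RMSE, plus window counts.

    ``rmse[label]`` is NaN when the label contributed no windows
    (reported with n = 0 rather than omitted).
    """

    rmse: dict[str, float]
    n_windows: dict[str, int]
    window_s: float | None = 1.0
    mad: dict[int, float] = field(default_factory=dict)
    mad_counts: dict[int, int] = field(default_factory=dict)

    def to_text(self) -> str:
        lines = [f"{'activity':<24}{'RMSE_deg':>10}{'n':>8}"]
        for label, value in self.rmse.items():
            shown = "n/a" if math.isnan(value) else f"{value:.3f}"
            lines.append(f"{label:<24}{shown:>10}{self.n_windows[label]:>8}")
        return "\n".join(lines)

    def write_tsv(self, path: str | Path) -> None:
        lines = ["activity\trmse_deg\tn_windows"]
        for label, value in self.rmse.items():
            shown = "nan" if math.isnan(value) else f"{value:.6g}"
            lines.append(f"{label}\t{shown}\t{self.n_windows[label]}")
        Path(path).write_text("\n".join(lines) + "\n")


def window_average(
    series: np.ndarray,
    sample_rate: float,
    window_s: float = 1.0,
    mask: np.ndarray | None = None,
):
    """Means over non-overlapping windows anchored at the series start.

    Each output is the mean of the unmasked samples in its window; a
    fully masked window yields a masked (NaN) output.  A partial
    trailing window is kept if at least half of its samples are
    unmasked.

    Returns (values, out_mask) with out_mask True where the window is
    masked.
    """
    series = np.asarray(series, float)
    if mask is None:
        mask = np.zeros(series.shape[0], dtype=bool)
    w = max(1, int(round(window_s * sample_rate)))
    if window_s * sample_rate < 1.0:
        raise ValueError("window must cover at least one sample period")
    values, out_mask = [], []
    for start in range(0, series.shape[0], w):
        chunk = series[start : start + w]
        cmask = mask[start : start + w]
        good = ~cmask
        is_trailing = chunk.shape[0] < w
        keep = good.mean() >= 0.5 if is_trailing else good.any()
        if is_trailing and not keep:
            continue
        if good.any():
            values.append(float(chunk[good].mean()))
            out_mask.append(False)
        else:
            values.append(np.nan)
            out_mask.append(True)
    return np.asarray(values), np.asarray(out_mask, dtype=bool)


def _segment_window_diffs(
    est, ref, sample_rate, start_time, t0, t1, window_s, mask
):
    """Windowed mean differences for one segment, windows anchored at t0."""
    i0 = max(0, int(np.ceil((t0 - start_time) * sample_rate - 1e-9)))
    i1 = min(est.shape[0], int(np.floor((t1 - start_time) * sample_rate + 1e-9)) + 1)
    if i1 <= i0:
        return np.asarray([])
    diff = est[i0:i1] - ref[i0:i1]
    seg_mask = mask[i0:i1]
    if window_s is None:
        return diff[~seg_mask]
    vals, out_mask = window_average(diff, sample_rate, window_s, mask=seg_mask)
    return vals[~out_mask]


def rmse_report(
    est: np.ndarray,
    ref: np.ndarray,
    segments: ActivitySegments,
    sample_rate: float,
    window_s: float | None = 1.0,
    mask: np.ndarray | None = None,
    start_time: float = 0.0,
) -> EvaluationReport:
    """Per-activity RMSE between aligned estimator and reference series.

    Windows are anchored at each segment start.  The overall entry pools
    every labeled window, so overall RMSE^2 equals the window-count-
    weighted mean of the per-activity RMSE^2.
    """
    est = np.asarray(est, float)
    ref = np.asarray(ref, float)
    if est.shape != ref.shape:
        raise ValueError(f"series misaligned: {est.shape} vs {ref.shape}")
    if mask is None:
        mask = np.zeros(est.shape[0], dtype=bool)
    per_label: dict[str, list[np.ndarray]] = {}
    for label, t0, t1 in segments:
        d = _segment_window_diffs(est, ref, sample_rate, start_time, t0, t1, window_s, mask)
        per_label.setdefault(label, []).append(d)
    rmse: dict[str, float] = {}
    n_windows: dict[str, int] = {}
    pooled: list[np.ndarray] = []
    for label, chunks in per_label.items():
        d = np.concatenate(chunks) if chunks else np.asarray([])
        n_windows[label] = d.size
        rmse[label] = float(np.sqrt(np.mean(d**2))) if d.size else float("nan")
        pooled.append(d)
    alld = np.concatenate(pooled) if pooled else np.asarray([])
    n_windows[OVERALL_LABEL] = alld.size
    rmse[OVERALL_LABEL] = float(np.sqrt(np.mean(alld**2))) if alld.size else float("nan")
    return EvaluationReport(rmse=rmse, n_windows=n_windows, window_s=window_s)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def mad_histogram(
    est: np.ndarray, ref: np.ndarray, mask: np.ndarray | None = None
) -> tuple[dict[int, float], dict[int, int]]:
    """Mean absolute difference binned by rounded reference angle.

    Bin key: reference angle rounded to the nearest whole degree
    (half-away-from-zero at .5 boundaries).  Returns ({bin: MAD},
    {bin: count}); counts partition the compared samples.
    """
    est = np.asarray(est, float)
    ref = np.asarray(ref, float)
    if est.shape != ref.shape:
        raise ValueError(f"series misaligned: {est.shape} vs {ref.shape}")
    if mask is not None:
        est, ref = est[~mask], ref[~mask]
    bins = _round_half_away(ref).astype(int)
    absdiff = np.abs(est - ref)
    mad: dict[int, float] = {}
    counts: dict[int, int] = {}
    for b in np.unique(bins):
        sel = bins == b
        mad[int(b)] = float(absdiff[sel].mean())
        counts[int(b)] = int(sel.sum())
    return mad, counts
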