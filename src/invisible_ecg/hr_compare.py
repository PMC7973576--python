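"""Matched-beat heart-rate comparison between the reference and an
experimental channel: detection ratio, instantaneous HR, HR difference,
signal detection error and the unpaired t-test.

These are the per-channel summary statistics used to judge whether a
dry-electrode channel reproduces the gold-standard heart rate: the beat
count ratio (values above 100% indicate spurious detections), the matched
per-interval HR difference, the percentage of the acquisition lost to
saturation or gross corruption (SDE), and a Welch two-sided t-test between
the two HR distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import UndefinedStatisticError
from .preprocessing import BeatLabel, BeatSeries

#: Resting heart-rate plausibility band (BPM); values outside are flagged.
RESTING_HR_BAND = (60.0, 100.0)


@dataclass
class MatchedBeats:
    """Greedy nearest-in-time pairing of reference and experimental beats.

    ``pairs`` holds positional indices into the two beat series;
    ``ref_r_indices`` / ``exp_r_indices`` are the series' R sample indices,
    so downstream stages can map a pair back to waveform positions.
    """

    pairs: list[tuple[int, int]]
    unmatched_ref: list[int]
    unmatched_exp: list[int]
    tolerance_ms: float
    ref_r_indices: np.ndarray | None = None
    exp_r_indices: np.ndarray | None = None


@dataclass
class ComparisonStats:
    """Per-channel comparison summary (detection ratio, HR, delta-HR, SDE, p)."""

    delta_qrs_percent: float
    hr_ref_mean: float
    hr_ref_sd: float
    hr_exp_mean: float
    hr_exp_sd: float
    dhr_mean: float
    dhr_sd: float
    sde_percent: float
    p_value: float
    n_matched: int

    def as_dict(self) -> dict:
        return {
            "delta_qrs_percent": self.delta_qrs_percent,
            "hr_ref": {"mean": self.hr_ref_mean, "sd": self.hr_ref_sd},
            "hr_exp": {"mean": self.hr_exp_mean, "sd": self.hr_exp_sd},
            "dhr": {"mean": self.dhr_mean, "sd": self.dhr_sd},
            "sde_percent": self.sde_percent,
            "p_value": self.p_value,
            "n_matched": self.n_matched,
        }


def match_rpeaks(ref: BeatSeries, exp: BeatSeries, tolerance_ms: float = 150.0) -> MatchedBeats:
    """Pair beats across channels, nearest in time first, each used once.

    Candidate (ref, exp) pairs within ``tolerance_ms`` are accepted in order
    of increasing absolute time difference. The default tolerance of 150 ms
    is half the minimum plausible RR interval (at 200 BPM), so a beat can
    never be matched across its neighbour.
    """
    if ref.n_beats == 0:
        raise UndefinedStatisticError("empty reference beat series")
    t_ref = ref.r_times * 1000.0
    t_exp = exp.r_times * 1000.0
    pairs: list[tuple[int, int]] = []
    if exp.n_beats:
        diffs = np.abs(t_exp[None, :] - t_ref[:, None])
        order = np.argsort(diffs, axis=None, kind="stable")
        used_r: set[int] = set()
        used_e: set[int] = set()
        for flat in order:
            i, j = divmod(int(flat), t_exp.size)
            if diffs[i, j] > tolerance_ms:
                break
            if i in used_r or j in used_e:
                continue
            used_r.add(i)
            used_e.add(j)
            pairs.append((i, j))
    matched_r = {i for i, _ in pairs}
    matched_e = {j for _, j in pairs}
    return MatchedBeats(
        pairs=sorted(pairs),
        unmatched_ref=[i for i in range(ref.n_beats) if i not in matched_r],
        unmatched_exp=[j for j in range(exp.n_beats) if j not in matched_e],
        tolerance_ms=tolerance_ms,
        ref_r_indices=ref.r_indices.copy(),
        exp_r_indices=exp.r_indices.copy(),
    )


def delta_qrs_percent(ref: BeatSeries, exp: BeatSeries) -> float:
    """Detected-beat count of the experimental channel as % of the reference.

    Computed on the full series before matching; >100% means spurious extra
    detections on the experimental channel.
    """
    if ref.n_beats == 0:
        raise UndefinedStatisticError("delta_qrs undefined for empty reference")
    return 100.0 * exp.n_beats / ref.n_beats


def instantaneous_hr(series: BeatSeries) -> tuple[np.ndarray, np.ndarray]:
    """Per-interval heart rate, ``HR_k = 60000 / RR_k(ms)``.

    Only intervals between consecutive beats both labelled normal are used.
    Returns ``(hr_bpm, out_of_band)`` where the flag marks values outside
    the 60-100 BPM resting band (kept, but advisory: a rerun is suggested
    when resting HR falls outside the estimated range).
    """
    idx = series.r_indices
    hr, flags = [], []
    for k in range(idx.size - 1):
        if (
            series.labels[k] == BeatLabel.NORMAL
            and series.labels[k + 1] == BeatLabel.NORMAL
        ):
            rr_ms = (idx[k + 1] - idx[k]) / series.fs * 1000.0
            bpm = 60000.0 / rr_ms
            hr.append(bpm)
            flags.append(not RESTING_HR_BAND[0] <= bpm <= RESTING_HR_BAND[1])
    return np.asarray(hr), np.asarray(flags, dtype=bool)


def delta_hr(ref: BeatSeries, exp: BeatSeries, matches: MatchedBeats) -> tuple[float, float, np.ndarray]:
    """Mean and sample SD (ddof 1) of matched per-interval HR differences.

    An HR value needs two beats, so differences are formed over consecutive
    matched pairs: for successive matches (i1, j1), (i2, j2) the reference
    HR comes from ref beats i1..i2 and the experimental HR from exp beats
    j1..j2, and ``d = HR_exp - HR_ref`` (sign convention: experimental minus
    reference). Returns ``(mean, sd, differences)``.
    """
    if not matches.pairs:
        raise UndefinedStatisticError("no matched beats: delta-HR undefined")
    pairs = matches.pairs
    t_ref = ref.r_times
    t_exp = exp.r_times
    d = []
    for (i1, j1), (i2, j2) in zip(pairs[:-1], pairs[1:]):
        rr_ref = t_ref[i2] - t_ref[i1]
        rr_exp = t_exp[j2] - t_exp[j1]
        if rr_ref <= 0 or rr_exp <= 0:
            continue
        d.append(60.0 / rr_exp - 60.0 / rr_ref)
    if not d:
        raise UndefinedStatisticError("fewer than two matched beats: delta-HR undefined")
    d = np.asarray(d)
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return float(d.mean()), sd, d


def signal_detection_error(
    raw,
    adc_bits: int,
    fs: float,
    min_run_ms: float = 50.0,
    corrupt_win_s: float = 1.0,
    corrupt_factor: float = 5.0,
) -> float:
    """Percentage of samples outside the valid measurement range (SDE, %).

    A sample is "outside" when it sits in a run of at least ``min_run_ms``
    clamped at an ADC rail (0 or full scale — the signature of contact loss
    saturating the front end), or inside a 1-s segment flagged as highly
    corrupted. Corruption is judged per non-overlapping ``corrupt_win_s``
    segment: a segment containing no rail samples whose standard deviation
    exceeds ``corrupt_factor`` times the median segment SD is counted in
    full. Segments containing rail-clamped samples are excluded from the
    corruption rule so clamp transitions are not double counted.
    """
    x = np.asarray(raw)
    if x.size == 0:
        raise UndefinedStatisticError("SDE undefined for empty input")
    rail_hi = 2**adc_bits - 1
    at_rail = (x == 0) | (x == rail_hi)

    outside = np.zeros(x.size, dtype=bool)
    min_run = max(1, int(round(min_run_ms * fs / 1000.0)))
    # runs of consecutive rail samples
    edges = np.diff(at_rail.astype(np.int8), prepend=0, append=0)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    for s, e in zip(starts, ends):
        if e - s >= min_run:
            outside[s:e] = True

    win = max(1, int(round(corrupt_win_s * fs)))
    n_seg = x.size // win
    if n_seg >= 2:
        seg = x[: n_seg * win].reshape(n_seg, win)
        seg_sd = seg.std(axis=1)
        clamp_free = ~at_rail[: n_seg * win].reshape(n_seg, win).any(axis=1)
        if clamp_free.any():
            med = np.median(seg_sd[clamp_free])
            bad = clamp_free & (seg_sd > corrupt_factor * med) & (med > 0)
            for k in np.flatnonzero(bad):
                outside[k * win : (k + 1) * win] = True

    return 100.0 * float(outside.mean())


def unpaired_ttest(a, b) -> float:
    """Two-sided Welch (unequal-variance) t-test p-value between two samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise UndefinedStatisticError("t-test needs >= 2 values per sample")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 1.0
        raise UndefinedStatisticError("both samples degenerate with unequal means")
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def compare_channels(
    ref: BeatSeries,
    exp: BeatSeries,
    raw_exp,
    adc_bits: int,
    fs: float,
    tolerance_ms: float = 150.0,
) -> ComparisonStats:
    """Full per-channel comparison row (detection ratio, HR, delta-HR, SDE, p)."""
    matches = match_rpeaks(ref, exp, tolerance_ms)
    dq = delta_qrs_percent(ref, exp)
    hr_ref, _ = instantaneous_hr(ref)
    hr_exp, _ = instantaneous_hr(exp)
    dmean, dsd, _ = delta_hr(ref, exp, matches)
    sde = signal_detection_error(raw_exp, adc_bits, fs)
    if hr_ref.size >= 2 and hr_exp.size >= 2:
        try:
            p = unpaired_ttest(hr_exp, hr_ref)
        except UndefinedStatisticError:
            p = float("nan")
    else:
        p = float("nan")

    def _stats(v: np.ndarray) -> tuple[float, float]:
        if v.size == 0:
            return float("nan"), float("nan")
        return float(v.mean()), float(v.std(ddof=1)) if v.size > 1 else 0.0

    hr_ref_mean, hr_ref_sd = _stats(hr_ref)
    hr_exp_mean, hr_exp_sd = _stats(hr_exp)
    return ComparisonStats(
        delta_qrs_percent=dq,
        hr_ref_mean=hr_ref_mean,
        hr_ref_sd=hr_ref_sd,
        hr_exp_mean=hr_exp_mean,
        hr_exp_sd=hr_exp_sd,
        dhr_mean=dmean,
        dhr_sd=dsd,
        sde_percent=sde,
        p_value=p,
        n_matched=len(matches.pairs),
    )
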