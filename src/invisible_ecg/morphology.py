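"""Beat-morphology quality control and cross-channel waveform scoring.

Two steps: DMEAN outlier rejection of beat templates, then Pearson
correlation (PCC) and range-normalized RMSE (NRMSE) between matched
reference/experimental beats that survived rejection.

DMEAN rule
----------
Given the beat templates x_i and their mean template mu, compute the
per-sample deviation D = x_i - mu for every beat, then the mean mu_D and
standard deviation sigma_D of |D| pooled over all beats and samples. A
sample is flagged when |D| > mu_D + 0.5 sigma_D; the "true positive"
percentage of a beat is the share of its samples *not* flagged. A beat is
kept when TP > 70% (default), otherwise labelled an outlier. The TP
denominator is the template length, so the rule applies to any window
size; the deviation is taken in absolute value so positive and negative
excursions count symmetrically.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import InsufficientDataError, UndefinedStatisticError
from .hr_compare import MatchedBeats
from .preprocessing import BeatLabel, BeatTemplateSet


@dataclass
class MorphologyScores:
    """Per-recording morphology agreement between two channels."""

    pcc_values: np.ndarray
    nrmse_values: np.ndarray
    kept_fraction_ref: float
    kept_fraction_exp: float

    @property
    def n_scored(self) -> int:
        return self.pcc_values.size

    def _mean_sd(self, v: np.ndarray) -> tuple[float, float]:
        sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
        return float(v.mean()), sd

    def as_dict(self) -> dict:
        pcc_mean, pcc_sd = self._mean_sd(self.pcc_values)
        nr_mean, nr_sd = self._mean_sd(self.nrmse_values)
        return {
            "pcc": {"mean": pcc_mean, "sd": pcc_sd},
            "nrmse_percent": {"mean": nr_mean, "sd": nr_sd},
            "kept_fraction_ref": self.kept_fraction_ref,
            "kept_fraction_exp": self.kept_fraction_exp,
            "n_scored": self.n_scored,
        }


def dmean_classify(tset: BeatTemplateSet, tp_threshold: float = 70.0) -> BeatTemplateSet:
    """Label each beat normal/outlier by the DMEAN TP rule.

    Returns a new :class:`BeatTemplateSet` with ``distances``, ``mu_d``,
    ``sigma_d``, ``tp_percent`` and ``labels`` filled in; a beat is kept iff
    its TP percentage strictly exceeds ``tp_threshold``.

    Raises
    ------
    InsufficientDataError
        With fewer than 3 templates the mean/SD of deviations is not a
        meaningful reference.
    """
    if tset.n_beats < 3:
        raise InsufficientDataError(
            f"DMEAN needs >= 3 templates, got {tset.n_beats}"
        )
    mu = tset.templates.mean(axis=0)
    d = tset.templates - mu[None, :]
    abs_d = np.abs(d)
    mu_d = float(abs_d.mean())
    sigma_d = float(abs_d.std(ddof=1))
    bound = mu_d + 0.5 * sigma_d
    # tiny absolute guard so numerically identical beats (D within float
    # rounding of zero) are never flagged
    guard = 1e-9 * max(float(np.abs(tset.templates).max()), 1.0)
    flagged = abs_d > bound + guard
    tp = 100.0 * (1.0 - flagged.mean(axis=1))
    labels = [
        BeatLabel.NORMAL if t > tp_threshold else BeatLabel.OUTLIER for t in tp
    ]
    return replace(
        tset,
        distances=d,
        mu_d=mu_d,
        sigma_d=sigma_d,
        tp_percent=tp,
        labels=labels,
    )


def pcc(x, y) -> float:
    """Pearson correlation coefficient between two equal-length waveforms."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise UndefinedStatisticError("pcc needs two equal-length waveforms (n >= 2)")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum()) * np.sqrt((yc**2).sum())
    if denom == 0:
        raise UndefinedStatisticError("pcc undefined for a constant waveform")
    return float((xc * yc).sum() / denom)


def nrmse(ref, exp) -> float:
    """RMSE between waveforms, as % of the reference peak-to-peak range."""
    ref = np.asarray(ref, dtype=float)
    exp = np.asarray(exp, dtype=float)
    if ref.size != exp.size or ref.size < 2:
        raise UndefinedStatisticError("nrmse needs two equal-length waveforms (n >= 2)")
    rng = float(np.ptp(ref))
    if rng == 0:
        raise UndefinedStatisticError("nrmse undefined for a flat reference")
    return 100.0 * float(np.sqrt(((ref - exp) ** 2).mean())) / rng


def score_recording(
    ref_tset: BeatTemplateSet,
    exp_tset: BeatTemplateSet,
    matches: MatchedBeats,
) -> MorphologyScores:
    """PCC/NRMSE over matched beat pairs kept by DMEAN on both channels.

    Both template sets must have been through :func:`dmean_classify`.
    Matching is by R index: a matched pair is scored when both its beats
    have full-window templates and both are labelled normal.

    Raises
    ------
    UndefinedStatisticError
        If no matched pair survives (all outliers or no overlap).
    """
    if ref_tset.labels is None or exp_tset.labels is None:
        raise UndefinedStatisticError("template sets must be DMEAN-classified first")
    if matches.ref_r_indices is None or matches.exp_r_indices is None:
        raise UndefinedStatisticError("matches must carry the beat sample indices")
    ref_pos = {int(r): k for k, r in enumerate(ref_tset.r_indices)}
    exp_pos = {int(r): k for k, r in enumerate(exp_tset.r_indices)}
    ref_kept = ref_tset.kept_mask()
    exp_kept = exp_tset.kept_mask()

    pccs, nrmses = [], []
    for i, j in matches.pairs:
        kr = ref_pos.get(int(matches.ref_r_indices[i]))
        ke = exp_pos.get(int(matches.exp_r_indices[j]))
        if kr is None or ke is None or not (ref_kept[kr] and exp_kept[ke]):
            continue
        ref_w = ref_tset.templates[kr]
        exp_w = exp_tset.templates[ke]
        try:
            pccs.append(pcc(ref_w, exp_w))
            nrmses.append(nrmse(ref_w, exp_w))
        except UndefinedStatisticError:
            continue
    if not pccs:
        raise UndefinedStatisticError("zero scorable matched beat pairs")
    return MorphologyScores(
        pcc_values=np.asarray(pccs),
        nrmse_values=np.asarray(nrmses),
        kept_fraction_ref=100.0 * ref_kept.mean(),
        kept_fraction_exp=100.0 * exp_kept.mean(),
    )
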