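"""Empirical-CDF calibration of raw scores to false negative rates (FNR).

Raw network probabilities depend strongly on hyperparameters such as the
absence ratio, so maps from differently configured models are not directly
comparable.  The fix: convert a score *s* to the fraction of known-presence
training examples whose score falls strictly below *s* — the false negative
rate that a detection threshold at *s* would incur on the reference
presences.  FNR values are "risk percentiles": an FNR of 0.5 at some
date-location means an observer there is better placed to see a mosquito
than at half of the date-locations where one was actually recorded.

Ties count as detected (strict-below counting), the conservative choice.
The empirical CDF is used as-is — a step function, no smoothing.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin


class FNRCalibrator(BaseEstimator, TransformerMixin):
    """Monotone score -> FNR transform from a reference presence population.

    ``fit`` takes the raw scores of the training-split presence examples
    (never pseudo-absences, never test rows); ``transform`` maps any score
    array through the empirical strict-below CDF.

    Fitted attributes: ``reference_`` (sorted ascending), ``n_ref_``.
    """

    def fit(self, scores, y=None):
        scores = np.asarray(scores, dtype=float).ravel()
        if scores.size < 2:
            raise ValueError("calibration reference needs at least 2 presence scores")
        if not np.all((scores > 0) & (scores < 1)):
            raise ValueError("reference scores must lie in (0, 1)")
        self.reference_ = np.sort(scores)
        self.n_ref_ = scores.size
        return self

    def transform(self, scores):
        """FNR(s) = #{reference < s} / N_ref, elementwise; NaN propagates."""
        if not hasattr(self, "reference_"):
            raise ValueError("FNRCalibrator is not fitted")
        s = np.asarray(scores, dtype=float)
        out = np.full(s.shape, np.nan)
        ok = np.isfinite(s)
        out[ok] = np.searchsorted(self.reference_, s[ok], side="left") / self.n_ref_
        return out if out.ndim else float(out)


def fnr_transform(score, reference) -> float | np.ndarray:
    """Functional wrapper: strict-below empirical CDF of ``reference`` at ``score``."""
    return FNRCalibrator().fit(reference).transform(score)


def calibrate_map(raw_map: np.ndarray, calibrator: FNRCalibrator) -> np.ndarray:
    """Elementwise FNR transform of a raster of raw scores; NaN cells propagate."""
    return calibrator.transform(np.asarray(raw_map, dtype=float))


def uniformity_check(held_out_presence_fnrs) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov test of held-out presence FNRs against
    Uniform(0, 1).

    If the calibration is faithful and held-out presences are exchangeable
    with the reference presences, these FNRs are approximately uniform.
    Returns (KS statistic, p-value).
    """
    vals = np.asarray(held_out_presence_fnrs, dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no finite FNR values to test")
    res = stats.kstest(vals, "uniform")
    return float(res.statistic), float(res.pvalue)
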