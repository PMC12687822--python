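"""Pseudo-absence generation, dataset assembly, splits and CV folds.

Pseudo-absences are background points for the presence-only classifier: a
date drawn uniformly within the window of presence observations, and a land
cell drawn with probability proportional to the cosine of its center
latitude (area-proportional on the sphere).  A draw is rejected when its
cell is shared with any presence observation, or when its date leaves too
little climate history for the configured sequence length.

The *absence ratio* is the presence : pseudo-absence count ratio; 0.2 means
five pseudo-absences per presence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import features as feat
from .grid_io import OBS_COLUMNS, LandMask

logger = logging.getLogger(__name__)


class SamplingError(RuntimeError):
    pass


@dataclass
class SamplingConfig:
    absence_ratio: float = 0.2
    rng_seed: int = 0
    max_rejection_attempts: int = 1000
    test_fraction: float = 0.2

    def __post_init__(self):
        if not (0.0 < self.absence_ratio <= 1.0):
            raise ValueError("absence_ratio must be in (0, 1]")


@dataclass
class LabeledDataset:
    """Feature matrix + labels + per-row metadata for one experiment."""

    X: np.ndarray
    y: np.ndarray
    meta: pd.DataFrame  # columns of OBS_COLUMNS
    variables: tuple = feat.DERIVED_VARS
    seq_len: int = 0

    def __post_init__(self):
        assert len(self.X) == len(self.y) == len(self.meta)
        pres_cells = set(map(tuple, self.meta.loc[self.meta.label == 1, ["cell_row", "cell_col"]].itertuples(index=False)))
        abs_cells = set(map(tuple, self.meta.loc[self.meta.label == 0, ["cell_row", "cell_col"]].itertuples(index=False)))
        shared = pres_cells & abs_cells
        if shared:
            raise AssertionError(f"pseudo-absence shares a cell with a presence: {sorted(shared)[:5]}")

    def subset(self, idx) -> "LabeledDataset":
        idx = np.asarray(idx)
        return LabeledDataset(
            self.X[idx], self.y[idx], self.meta.iloc[idx].reset_index(drop=True),
            self.variables, self.seq_len,
        )

    def __len__(self) -> int:
        return len(self.y)


def sample_pseudo_absences(
    n: int,
    mask: LandMask,
    presence_cells: set[tuple[int, int]],
    window: tuple,
    rng: np.random.Generator,
    *,
    min_date=None,
    species: str = "pseudo",
) -> pd.DataFrame:
    """Draw ``n`` pseudo-absence records.

    Cells: land cells weighted by cos(center latitude), rejecting presence
    cells.  Dates: uniform over [window[0], window[1]]; when ``min_date`` is
    given, dates earlier than it are rejected and redrawn (sequence-history
    guard).  Duplicate (cell, date) pairs are allowed — draws are
    independent.
    """
    land = mask.land_indices
    lat_centers = mask.grid.lat_centers
    weights = np.cos(np.deg2rad(lat_centers[land[:, 0]]))
    valid = np.array([tuple(c) not in presence_cells for c in land])
    if not valid.any():
        raise SamplingError("no land cell free of presence observations")
    weights = np.where(valid, weights, 0.0)
    total = weights.sum()
    if total <= 0:
        raise SamplingError("all presence-free land cells have zero sampling weight")
    p = weights / total

    d0, d1 = pd.Timestamp(window[0]).normalize(), pd.Timestamp(window[1]).normalize()
    if d1 < d0:
        raise SamplingError("empty presence date window")
    if min_date is not None and pd.Timestamp(min_date) > d1:
        raise SamplingError("no date in the window leaves enough climate history")
    n_days = (d1 - d0).days + 1

    picks = rng.choice(len(land), size=n, p=p)
    offsets = rng.integers(0, n_days, size=n)
    if min_date is not None:
        min_off = (pd.Timestamp(min_date).normalize() - d0).days
        bad = offsets < min_off
        attempts = 0
        while bad.any():
            attempts += 1
            if attempts > 1000:
                raise SamplingError("rejection budget exhausted drawing valid dates")
            offsets[bad] = rng.integers(min_off, n_days, size=int(bad.sum()))
            bad = offsets < min_off
    dates = d0 + pd.to_timedelta(offsets, unit="D")
    cells = land[picks]
    lat = lat_centers[cells[:, 0]]
    lon = mask.grid.lon_centers[cells[:, 1]]
    return pd.DataFrame(
        {
            "species": species,
            "date": dates,
            "lat": lat,
            "lon": lon,
            "label": 0,
            "cell_row": cells[:, 0],
            "cell_col": cells[:, 1],
            "provenance": "pseudo_absence",
        },
        columns=OBS_COLUMNS,
    )


def build_dataset(
    presences: pd.DataFrame,
    config: SamplingConfig,
    mask: LandMask,
    derived,
    seq_len: int,
    variables=feat.DERIVED_VARS,
    rng: np.random.Generator | None = None,
) -> LabeledDataset:
    """Join presences with n_presence / absence_ratio pseudo-absences and
    their flattened climate sequences.

    Presence rows lacking ``seq_len`` days of history are dropped with a
    count; pseudo-absence dates are constrained at draw time.
    """
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    all_dates = pd.DatetimeIndex(derived.time.values)
    min_date = all_dates[0] + pd.Timedelta(days=seq_len)
    max_date = all_dates[-1] + pd.Timedelta(days=1)

    pres = presences[presences.label == 1].copy()
    ok = (pd.DatetimeIndex(pres.date) >= min_date) & (pd.DatetimeIndex(pres.date) <= max_date)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("build_dataset: dropped %d presences lacking climate history", n_dropped)
    pres = pres[ok].reset_index(drop=True)
    if len(pres) == 0:
        raise SamplingError("no presence with computable features")

    n_pseudo = int(round(len(pres) / config.absence_ratio))
    window = (pres.date.min(), min(pres.date.max(), max_date))
    presence_cells = set(zip(pres.cell_row.astype(int), pres.cell_col.astype(int)))
    absences = sample_pseudo_absences(
        n_pseudo, mask, presence_cells, window, rng, min_date=min_date
    )
    meta = pd.concat([pres, absences], ignore_index=True)
    cells = meta[["cell_row", "cell_col"]].to_numpy(dtype=int)
    X = feat.assemble_matrix(derived, cells, meta.date, seq_len, variables)
    y = meta.label.to_numpy(dtype=int)
    return LabeledDataset(X, y, meta, tuple(variables), seq_len)


def split_random(
    dataset: LabeledDataset, test_fraction: float = 0.2, rng: np.random.Generator | None = None
) -> tuple[LabeledDataset, LabeledDataset]:
    """Random split: ``test_fraction`` of presences plus an equal count of
    pseudo-absences form the test set; everything else trains."""
    rng = rng if rng is not None else np.random.default_rng(0)
    pres_idx = np.flatnonzero(dataset.y == 1)
    abs_idx = np.flatnonzero(dataset.y == 0)
    n_test = int(round(test_fraction * len(pres_idx)))
    test_pres = rng.choice(pres_idx, size=n_test, replace=False)
    test_abs = rng.choice(abs_idx, size=n_test, replace=False)
    test_idx = np.sort(np.concatenate([test_pres, test_abs]))
    train_idx = np.setdiff1d(np.arange(len(dataset)), test_idx)
    return dataset.subset(train_idx), dataset.subset(test_idx)


def split_chronological(
    dataset: LabeledDataset, test_fraction: float = 0.2, rng: np.random.Generator | None = None
) -> tuple[LabeledDataset, LabeledDataset]:
    """Chronological split: the newest ``test_fraction`` of presences (ties
    broken by stable input order) plus an equal random count of
    pseudo-absences form the test set."""
    rng = rng if rng is not None else np.random.default_rng(0)
    pres_idx = np.flatnonzero(dataset.y == 1)
    abs_idx = np.flatnonzero(dataset.y == 0)
    n_test = int(round(test_fraction * len(pres_idx)))
    order = pres_idx[np.argsort(pd.DatetimeIndex(dataset.meta.date.iloc[pres_idx]).values, kind="stable")]
    test_pres = order[len(order) - n_test :]
    test_abs = rng.choice(abs_idx, size=n_test, replace=False)
    test_idx = np.sort(np.concatenate([test_pres, test_abs]))
    train_idx = np.setdiff1d(np.arange(len(dataset)), test_idx)
    return dataset.subset(train_idx), dataset.subset(test_idx)


def make_folds(train: LabeledDataset, k: int = 5, rng: np.random.Generator | None = None):
    """Label-stratified k-fold partition of the training set.

    Returns a list of (train_idx, val_idx) pairs; fold sizes differ by at
    most one and the positive fraction per fold matches the global fraction
    to within one row.
    """
    seed = int(rng.integers(2**31 - 1)) if rng is not None else 0
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(train.X, train.y))
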