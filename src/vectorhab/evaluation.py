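"""ROC/AUC evaluation, leave-one/two-out covariate ablation, and Jaccard
comparison of binarized risk maps.

The ablation harness retrains the classifier on every covariate subset of
the base set obtained by removing zero, one, or two variables, at each
requested sequence length and split type.  Because the feature matrix is
day-major with a fixed variable order, a subset model's features are a
column mask of the full matrix — the pseudo-absence pool and the split are
held fixed so AUC differences reflect covariates, not resampling.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import asdict

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from . import ffnn, sampling

logger = logging.getLogger(__name__)


def roc_auc(values, labels) -> float:
    """Rank-based AUC (ties contribute 1/2); identical on raw scores or FNRs."""
    return float(roc_auc_score(np.asarray(labels), np.asarray(values)))


def variable_subsets(base_variables, max_leave_out: int = 2) -> list[tuple]:
    """The full set plus every leave-one-out and leave-two-out subset.

    For 5 base variables: 1 + 5 + 10 = 16 subsets.
    """
    base = tuple(base_variables)
    if len(base) < 1:
        raise ValueError("need at least one base variable")
    out = [base]
    for n_out in range(1, max_leave_out + 1):
        if n_out >= len(base):
            break
        for drop in itertools.combinations(base, n_out):
            out.append(tuple(v for v in base if v not in drop))
    return out


def _column_mask(all_vars, subset, seq_len):
    """Columns of the day-major feature matrix belonging to ``subset``."""
    keep = np.array([v in subset for v in all_vars])
    return np.tile(keep, seq_len)


def ablation(
    dataset: sampling.LabeledDataset,
    config: ffnn.ModelConfig,
    base_variables=None,
    seq_lens=(30, 60, 90, 365),
    splits=("random", "chronological"),
    k: int = 5,
    max_leave_out: int = 2,
    derived=None,
    test_fraction: float = 0.2,
) -> pd.DataFrame:
    """Leave-one/two-out ablation over (subset, seq_len, split).

    ``dataset`` must carry features at the *longest* requested seq_len; a
    shorter sequence is the most recent days of the long one, so each
    (subset, seq_len) model trains on a column mask of the one matrix.
    Returns a tidy DataFrame with one row per (subset, seq_len, split),
    ranked per Fig-1C mechanics by the best AUC across sequence lengths.
    """
    base = tuple(base_variables) if base_variables is not None else dataset.variables
    if any(v not in dataset.variables for v in base):
        raise ValueError("base variables must be columns of the dataset")
    subsets = variable_subsets(base, max_leave_out)
    max_len = max(seq_lens)
    if dataset.seq_len < max_len:
        raise ValueError(f"dataset holds {dataset.seq_len} days; need {max_len}")

    rows = []
    for split_type in splits:
        rng = np.random.default_rng(config.seed)
        if split_type == "random":
            train_full, test_full = sampling.split_random(dataset, test_fraction, rng)
        elif split_type == "chronological":
            train_full, test_full = sampling.split_chronological(dataset, test_fraction, rng)
        else:
            raise ValueError(f"unknown split type {split_type!r}")
        folds = sampling.make_folds(train_full, k, np.random.default_rng(config.seed))
        for seq_len in seq_lens:
            # most recent seq_len days = trailing columns of the day-major matrix
            tail = slice((dataset.seq_len - seq_len) * len(dataset.variables), None)
            for subset in subsets:
                mask = _column_mask(dataset.variables, subset, seq_len)
                Xtr = train_full.X[:, tail][:, mask]
                Xte = test_full.X[:, tail][:, mask]
                cfg = ffnn.ModelConfig(**{**asdict(config),
                                          "seq_len": seq_len,
                                          "variable_subset": subset})
                sub_train = sampling.LabeledDataset(
                    Xtr, train_full.y, train_full.meta, subset, seq_len)
                cv = ffnn.cross_validate(sub_train, cfg, k=k, folds=folds)
                model = ffnn.fit_pipeline(sub_train, cfg)
                test_auc = roc_auc(model.predict_scores(Xte), test_full.y)
                rows.append({
                    "variable_subset": "+".join(subset),
                    "n_vars": len(subset),
                    "seq_len": seq_len,
                    "split_type": split_type,
                    "auc": test_auc,
                    "cv_mean_auc": cv["mean_auc"],
                    "fold_aucs": cv["fold_aucs"],
                })
                logger.info("ablation %s seq=%d %s: AUC=%.3f",
                            split_type, seq_len, "+".join(subset), test_auc)
    df = pd.DataFrame(rows)
    # Fig-1C ordering: subsets ranked by their best AUC over all seq lens,
    # ties broken lexicographically by subset name.
    best = df.groupby(["split_type", "variable_subset"])["auc"].transform("max")
    df["best_auc_all_seq_lens"] = best
    df = df.sort_values(
        ["split_type", "best_auc_all_seq_lens", "variable_subset", "seq_len"],
        ascending=[True, False, True, True],
    ).reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# map comparison
# ---------------------------------------------------------------------------

def jaccard_maps(map_a: np.ndarray, map_b: np.ndarray, threshold: float) -> float:
    """Intersection-over-union of the two maps' >= threshold exceedance sets.

    NaN cells belong to neither set.  Both sets empty -> 1.0 (identical
    predictions), logged when triggered.
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("maps must share a grid")
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    sa = np.nan_to_num(a, nan=-np.inf) >= threshold
    sb = np.nan_to_num(b, nan=-np.inf) >= threshold
    union = np.logical_or(sa, sb).sum()
    if union == 0:
        logger.info("jaccard_maps: both exceedance sets empty; defined as 1.0")
        return 1.0
    return float(np.logical_and(sa, sb).sum() / union)


def jaccard_matrix(map_a: np.ndarray, map_b: np.ndarray, thresholds) -> np.ndarray:
    """Jaccard similarity of (A at t_i) vs (B at t_j) for every threshold pair."""
    thresholds = list(thresholds)
    out = np.empty((len(thresholds), len(thresholds)))
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    for i, ti in enumerate(thresholds):
        sa = np.nan_to_num(a, nan=-np.inf) >= ti
        for j, tj in enumerate(thresholds):
            sb = np.nan_to_num(b, nan=-np.inf) >= tj
            union = np.logical_or(sa, sb).sum()
            out[i, j] = 1.0 if union == 0 else np.logical_and(sa, sb).sum() / union
    return out
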