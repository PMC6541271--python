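"""Saliency analysis of the trained surrogate.

Positive saliency is the rectified gradient of the predicted yield with
respect to every input cell, rescaled per map to a maximum of 1: the cells
whose increase most raises the predicted yield.  Signed gradients are kept
alongside for direction-of-effect readouts.  Maps are aggregated into
per-factor profiles over developmental-index (DVI) bins, for three cases:
all datasets, the low-hγH (heat-sterility) tail, and the low-hγL
(cool-summer) tail.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import Corpus, FACTORS
from .nn import CNNRegressor

CASE_NAMES = ("all", "low_h_gammaH", "low_h_gammaL")


class SaliencyError(ValueError):
    pass


@dataclass(frozen=True)
class CaseSpec:
    """Dataset subset used for a saliency case.

    ``low_h_gammaH``/``low_h_gammaL`` keep datasets at or below the given
    percentile of the heat-only / cool-only harvest index; the percentile
    threshold is computed on the corpus at hand.
    """

    name: str = "all"
    percentile: float = 10.0

    def __post_init__(self) -> None:
        if self.name not in CASE_NAMES:
            raise SaliencyError(f"unknown case {self.name!r}")
        if not 0.0 < self.percentile <= 100.0:
            raise SaliencyError("percentile must be in (0, 100]")


def saliency_gradients(model: CNNRegressor, x: np.ndarray,
                       batch: int = 128) -> np.ndarray:
    """Signed input gradients d(yield)/d(cell), shape like ``x``."""
    x = np.asarray(x)
    if x.ndim == 2:
        return model.input_gradient(x)
    out = np.empty(x.shape, dtype=np.float64)
    for i in range(0, len(x), batch):
        out[i:i + batch] = model.input_gradient(x[i:i + batch])
    return out


def rectify(grad: np.ndarray) -> np.ndarray:
    """Positive part of a gradient map, rescaled so max = 1 per map
    (identically zero maps stay zero)."""
    pos = np.maximum(grad, 0.0)
    if pos.ndim == 2:
        m = pos.max()
        return pos / m if m > 0 else pos
    peaks = pos.reshape(len(pos), -1).max(axis=1)
    safe = np.where(peaks > 0, peaks, 1.0)
    return pos / safe[:, None, None]


def positive_saliency(model: CNNRegressor, matrix: np.ndarray) -> np.ndarray:
    """Positive saliency map of one normalized input matrix."""
    return rectify(saliency_gradients(model, np.asarray(matrix)))


def select_case(h_gammaH: np.ndarray, h_gammaL: np.ndarray,
                case: CaseSpec) -> np.ndarray:
    """Indices of the datasets belonging to ``case``.

    Selection uses ``value <= percentile threshold`` on the relevant
    stress-specific harvest index.
    """
    n = len(h_gammaH)
    if n == 0:
        raise SaliencyError("no datasets to select from")
    if case.name == "all":
        return np.arange(n)
    values = np.asarray(h_gammaH if case.name == "low_h_gammaH" else h_gammaL,
                        dtype=float)
    thresh = np.percentile(values, case.percentile)
    idx = np.flatnonzero(values <= thresh)
    if idx.size == 0:
        raise SaliencyError(f"case {case.name!r} selected no datasets")
    return idx


def sample_inputs(subset: Sequence[int], n: int = 500,
                  seed: int = 0) -> np.ndarray:
    """Seeded sample of dataset indices: without replacement when the
    subset is large enough, otherwise with replacement."""
    subset = np.asarray(subset)
    if n == 0:
        return np.empty(0, dtype=int)
    if subset.size == 0:
        raise SaliencyError("cannot sample from an empty subset")
    rng = np.random.default_rng(seed)
    replace = subset.size < n
    return rng.choice(subset, size=n, replace=replace)


def profile_by_dvi(
    maps: np.ndarray,
    dvi_trajectories: np.ndarray,
    pad_mask: np.ndarray,
    bin_width: float = 0.05,
    case_label: str = "all",
) -> pd.DataFrame:
    """Mean saliency per meteorological factor and DVI bin.

    Each non-padded day-row of each map contributes its five factor
    saliencies to the bin holding that day's DVI; means are taken across
    all contributing (map, day) rows.  Tidy output: one row per
    (case, factor, dvi_bin).
    """
    maps = np.asarray(maps)
    dvi = np.asarray(dvi_trajectories)
    pad = np.asarray(pad_mask, dtype=bool)
    if maps.ndim != 3 or maps.shape[:2] != dvi.shape or pad.shape != dvi.shape:
        raise SaliencyError(
            f"unpaired inputs: maps {maps.shape}, dvi {dvi.shape}, "
            f"pad {pad.shape}")
    n_bins = int(np.ceil(2.0 / bin_width))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    mids = (edges[:-1] + edges[1:]) / 2.0

    live = ~pad
    vals = maps[live]                       # (n_rows, 5)
    bins = np.clip(np.digitize(dvi[live], edges) - 1, 0, n_bins - 1)

    rows = []
    for b in range(n_bins):
        sel = bins == b
        n_obs = int(sel.sum())
        for f, factor in enumerate(FACTORS):
            rows.append({
                "case": case_label,
                "factor": factor,
                "dvi_bin": mids[b],
                "mean_saliency": float(vals[sel, f].mean()) if n_obs else np.nan,
                "n_obs": n_obs,
            })
    return pd.DataFrame(rows)


def case_profiles(
    model: CNNRegressor,
    corpus: Corpus,
    cases: Sequence[CaseSpec] = tuple(CaseSpec(n) for n in CASE_NAMES),
    n_maps: int = 500,
    bin_width: float = 0.05,
    seed: int = 0,
    signed: bool = False,
) -> pd.DataFrame:
    """Saliency-vs-DVI profiles for each case, sampled from the training
    split (the maps' seeds are the training inputs, as in the distillation
    protocol)."""
    frames = []
    for k, case in enumerate(cases):
        subset = select_case(corpus.h_gammaH_train, corpus.h_gammaL_train, case)
        idx = sample_inputs(subset, n=n_maps, seed=seed + k)
        x = corpus.x_train[idx]
        grads = saliency_gradients(model, x)
        maps = grads if signed else rectify(grads)
        pad = np.all(x == 0.0, axis=2)
        frames.append(profile_by_dvi(maps, corpus.dvi_train[idx], pad,
                                     bin_width=bin_width,
                                     case_label=case.name))
    return pd.concat(frames, ignore_index=True)


def window_contrast_pvalue(
    maps: np.ndarray,
    dvi_trajectories: np.ndarray,
    pad_mask: np.ndarray,
    factor: str,
    window: tuple[float, float],
    seed: int = 0,
    n_permutations: int = 2000,
    closed_right: bool = True,
) -> tuple[float, float]:
    """Paired permutation test: does a factor's saliency differ inside a
    DVI window versus outside it?

    Per map, the mean saliency of the factor over non-padded days with DVI
    inside ``window`` is compared with the mean outside; the sign-flip
    permutation null (two-sided) gives the p-value.  Returns
    ``(mean_inside_minus_outside, p_value)``.
    """
    f = FACTORS.index(factor)
    lo, hi = window
    maps = np.asarray(maps)
    dvi = np.asarray(dvi_trajectories)
    live = ~np.asarray(pad_mask, dtype=bool)
    inside = (dvi > lo) & ((dvi <= hi) if closed_right else (dvi < hi)) & live
    outside = ~inside & live

    diffs = []
    for i in range(len(maps)):
        if inside[i].any() and outside[i].any():
            diffs.append(maps[i, inside[i], f].mean()
                         - maps[i, outside[i], f].mean())
    if len(diffs) < 2:
        raise SaliencyError("too few maps with days on both sides of the window")
    diffs = np.asarray(diffs)
    obs = diffs.mean()
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, len(diffs)))
    null = (signs * diffs).mean(axis=1)
    p = (1.0 + np.sum(np.abs(null) >= abs(obs))) / (n_permutations + 1.0)
    return float(obs), float(p)


def write_profiles(profiles: pd.DataFrame, path) -> None:
    profiles.to_csv(path, index=False)
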