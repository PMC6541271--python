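"""Training-corpus construction for the yield surrogate.

Turns simulator outputs into fixed-shape 184×5 input matrices (columns
``L, Tmean, Tmax, Ss, P`` — the meteorological factors; ``Ss`` here is the
incident daily global solar radiation), applies the exclusion filter,
post-maturity zero padding, train-split z-score normalization, uniform
noise injection, and the 75/25 random split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .simriw import SeasonResult
from .weather import SEASON_DAYS, WeatherSeries

FACTORS = ("L", "Tmean", "Tmax", "Ss", "P")
N_FACTORS = len(FACTORS)
#: index of the CO2 column, the only column allowed to be constant
P_COLUMN = 4


class DatasetError(ValueError):
    pass


@dataclass
class InputMatrix:
    """One 184×5 surrogate input with its target yield and DVI alignment.

    ``maturity_day`` is the 0-based day index on which DVI reached 2.0;
    rows strictly after it are zero-padded (the weather of the maturity day
    itself still acted on the crop).
    """

    values: np.ndarray  # (184, 5)
    target_yg: float
    dvi_by_day: np.ndarray  # (184,)
    grid_id: str
    year_index: int
    maturity_day: int
    h_gammaH: float = float("nan")
    h_gammaL: float = float("nan")

    @property
    def padded_rows(self) -> np.ndarray:
        """Boolean mask of zero-padded (post-maturity) rows."""
        mask = np.zeros(SEASON_DAYS, dtype=bool)
        mask[self.maturity_day + 1:] = True
        return mask


@dataclass
class NormStats:
    """Per-factor center/scale fitted on the training split only."""

    center: np.ndarray  # (5,)
    scale: np.ndarray  # (5,)

    def __post_init__(self) -> None:
        if np.any(self.scale <= 0):
            raise DatasetError("normalization scale must be > 0")

    def to_dict(self) -> dict:
        return {"center": self.center.tolist(), "scale": self.scale.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "NormStats":
        return cls(np.asarray(d["center"], float), np.asarray(d["scale"], float))


def make_matrix(weather: WeatherSeries, result: SeasonResult) -> InputMatrix:
    """Shape one grid-year into the surrogate's input layout.

    Columns in fixed order ``L, Tmean, Tmax, Ss, P``; rows after the
    maturity day are zeroed so every input has the same 184-row shape.
    """
    if result.excluded:
        raise DatasetError(
            f"{result.grid_id}/y{result.year_index}: excluded result cannot "
            "be shaped into a training matrix")
    if (weather.grid_id, weather.year_index) != (result.grid_id, result.year_index):
        raise DatasetError("weather/result metadata mismatch")
    values = np.column_stack([
        weather.day_len,
        weather.tmean,
        weather.tmax,
        weather.s_incident,
        weather.co2,
    ]).astype(float)
    m = result.maturity_day if result.maturity_day is not None else SEASON_DAYS - 1
    values[m + 1:, :] = 0.0
    return InputMatrix(
        values=values,
        target_yg=result.yg,
        dvi_by_day=result.dvi_by_day.copy(),
        grid_id=result.grid_id,
        year_index=result.year_index,
        maturity_day=int(m),
        h_gammaH=result.h_gammaH,
        h_gammaL=result.h_gammaL,
    )


def exclude_immature(results: Sequence[SeasonResult]) -> tuple[list[SeasonResult], list[SeasonResult]]:
    """Partition results into (kept, excluded) by the October-05 DVI rule."""
    kept = [r for r in results if not r.excluded]
    excluded = [r for r in results if r.excluded]
    return kept, excluded


def fit_normalizer(train_matrices: Sequence[InputMatrix]) -> NormStats:
    """Per-factor mean/sd over non-padded cells of the training split.

    The constant CO2 column falls back to identity scaling (center 0,
    scale 1); any other zero-variance column is an error.
    """
    if not train_matrices:
        raise DatasetError("training split is empty")
    stacked = np.concatenate(
        [m.values[~m.padded_rows] for m in train_matrices], axis=0)
    center = stacked.mean(axis=0)
    scale = stacked.std(axis=0)
    for j in range(N_FACTORS):
        if scale[j] < 1e-12:
            if j == P_COLUMN:
                center[j], scale[j] = 0.0, 1.0
            else:
                raise DatasetError(
                    f"zero-variance column {FACTORS[j]!r} in training split")
    return NormStats(center=center, scale=scale)


def apply_normalizer(matrix: InputMatrix, stats: NormStats) -> InputMatrix:
    """Z-score non-padded rows; padded rows remain exactly zero."""
    values = matrix.values.copy()
    live = ~matrix.padded_rows
    values[live] = (values[live] - stats.center) / stats.scale
    out = InputMatrix(**{**matrix.__dict__, "values": values})
    return out


def inverse_normalizer(matrix: InputMatrix, stats: NormStats) -> InputMatrix:
    values = matrix.values.copy()
    live = ~matrix.padded_rows
    values[live] = values[live] * stats.scale + stats.center
    return InputMatrix(**{**matrix.__dict__, "values": values})


def add_noise(matrix: InputMatrix, amplitude: float = 0.001,
              seed: int = 0) -> InputMatrix:
    """Perturb every cell by an independent uniform draw in
    [-amplitude, +amplitude]; padded rows are re-zeroed so the padding
    stays exactly zero."""
    if amplitude < 0:
        raise DatasetError("noise amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    values = matrix.values + rng.uniform(-amplitude, amplitude,
                                         size=matrix.values.shape)
    values[matrix.padded_rows] = 0.0
    return InputMatrix(**{**matrix.__dict__, "values": values})


def split(matrices: Sequence[InputMatrix], train_fraction: float = 0.75,
          seed: int = 0) -> tuple[list[InputMatrix], list[InputMatrix]]:
    """Seeded uniform random partition by grid-year unit."""
    if not 0.0 < train_fraction < 1.0:
        raise DatasetError("train_fraction must be in (0, 1)")
    n = len(matrices)
    if n < 4:
        raise DatasetError("need at least 4 matrices to split")
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    train = [matrices[i] for i in perm[:n_train]]
    val = [matrices[i] for i in perm[n_train:]]
    return train, val


# --- corpus container -----------------------------------------------------

@dataclass
class Corpus:
    """Normalized, noise-injected train/validation arrays plus alignment
    metadata needed downstream (DVI trajectories for saliency binning,
    stress-specific harvest indices for case selection)."""

    x_train: np.ndarray  # (n_train, 184, 5) float32
    y_train: np.ndarray  # (n_train,) raw g m-2
    dvi_train: np.ndarray  # (n_train, 184)
    h_gammaH_train: np.ndarray
    h_gammaL_train: np.ndarray
    meta_train: list[tuple[str, int]]
    x_val: np.ndarray
    y_val: np.ndarray
    dvi_val: np.ndarray
    h_gammaH_val: np.ndarray
    h_gammaL_val: np.ndarray
    meta_val: list[tuple[str, int]]
    stats: NormStats
    noise_amplitude: float
    train_fraction: float
    seed: int

    @property
    def n_train(self) -> int:
        return len(self.y_train)

    @property
    def n_val(self) -> int:
        return len(self.y_val)


def _stack(matrices: Sequence[InputMatrix]) -> tuple[np.ndarray, ...]:
    x = np.stack([m.values for m in matrices]).astype(np.float32)
    y = np.array([m.target_yg for m in matrices], dtype=np.float64)
    dvi = np.stack([m.dvi_by_day for m in matrices])
    hgh = np.array([m.h_gammaH for m in matrices])
    hgl = np.array([m.h_gammaL for m in matrices])
    meta = [(m.grid_id, m.year_index) for m in matrices]
    return x, y, dvi, hgh, hgl, meta


def build_corpus(
    weather_list: Sequence[WeatherSeries],
    results: Sequence[SeasonResult],
    noise_amplitude: float = 0.001,
    train_fraction: float = 0.75,
    seed: int = 0,
) -> Corpus:
    """Full corpus pipeline: filter → shape → split → normalize → noise.

    Normalization statistics come from the training split only; noise is
    applied after normalization to both splits, as in the distillation
    protocol this package implements.
    """
    by_key = {(w.grid_id, w.year_index): w for w in weather_list}
    kept, _ = exclude_immature(results)
    if not kept:
        raise DatasetError("no datasets survived exclusion")
    matrices = [make_matrix(by_key[(r.grid_id, r.year_index)], r) for r in kept]
    train, val = split(matrices, train_fraction, seed=seed)
    stats = fit_normalizer(train)
    rng = np.random.default_rng([seed, 1])
    noise_seeds = rng.integers(0, 2**31 - 1, size=len(train) + len(val))
    train = [
        add_noise(apply_normalizer(m, stats), noise_amplitude, int(s))
        for m, s in zip(train, noise_seeds[:len(train)])
    ]
    val = [
        add_noise(apply_normalizer(m, stats), noise_amplitude, int(s))
        for m, s in zip(val, noise_seeds[len(train):])
    ]
    xt, yt, dt, hht, hlt, mt = _stack(train)
    xv, yv, dv, hhv, hlv, mv = _stack(val)
    return Corpus(
        x_train=xt, y_train=yt, dvi_train=dt, h_gammaH_train=hht,
        h_gammaL_train=hlt, meta_train=mt,
        x_val=xv, y_val=yv, dvi_val=dv, h_gammaH_val=hhv,
        h_gammaL_val=hlv, meta_val=mv,
        stats=stats, noise_amplitude=noise_amplitude,
        train_fraction=train_fraction, seed=seed,
    )


def save_corpus(corpus: Corpus, path: str | Path) -> None:
    """Single array container (.npz) with a JSON provenance sidecar."""
    path = Path(path)
    np.savez_compressed(
        path,
        x_train=corpus.x_train, y_train=corpus.y_train,
        dvi_train=corpus.dvi_train,
        h_gammaH_train=corpus.h_gammaH_train,
        h_gammaL_train=corpus.h_gammaL_train,
        x_val=corpus.x_val, y_val=corpus.y_val, dvi_val=corpus.dvi_val,
        h_gammaH_val=corpus.h_gammaH_val, h_gammaL_val=corpus.h_gammaL_val,
        center=corpus.stats.center, scale=corpus.stats.scale,
    )
    sidecar = {
        "noise_amplitude": corpus.noise_amplitude,
        "train_fraction": corpus.train_fraction,
        "seed": corpus.seed,
        "n_train": corpus.n_train,
        "n_val": corpus.n_val,
        "meta_train": [[g, y] for g, y in corpus.meta_train],
        "meta_val": [[g, y] for g, y in corpus.meta_val],
        "norm_stats": corpus.stats.to_dict(),
    }
    path.with_suffix(".json").write_text(
        json.dumps(sidecar, indent=1), encoding="utf-8")


def load_corpus(path: str | Path) -> Corpus:
    path = Path(path)
    with np.load(path) as z:
        arrays = {k: z[k] for k in z.files}
    sidecar = json.loads(path.with_suffix(".json").read_text(encoding="utf-8"))
    return Corpus(
        x_train=arrays["x_train"], y_train=arrays["y_train"],
        dvi_train=arrays["dvi_train"],
        h_gammaH_train=arrays["h_gammaH_train"],
        h_gammaL_train=arrays["h_gammaL_train"],
        meta_train=[(g, int(y)) for g, y in sidecar["meta_train"]],
        x_val=arrays["x_val"], y_val=arrays["y_val"],
        dvi_val=arrays["dvi_val"],
        h_gammaH_val=arrays["h_gammaH_val"],
        h_gammaL_val=arrays["h_gammaL_val"],
        meta_val=[(g, int(y)) for g, y in sidecar["meta_val"]],
        stats=NormStats.from_dict(sidecar["norm_stats"]),
        noise_amplitude=float(sidecar["noise_amplitude"]),
        train_fraction=float(sidecar["train_fraction"]),
        seed=int(sidecar["seed"]),
    )
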