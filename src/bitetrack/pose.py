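"""Body-part pose analysis: ingestion, egocentric alignment, wavelet
features, and low-dimensional embedding.

Pose tables come from a markerless pose estimator in the common
three-header-row CSV dialect (scorer / bodyparts / coords with x, y,
likelihood per part). Coordinates are re-expressed in a body-fixed frame
(origin at the abdominal tip, +x toward the abdomen center, i.e.
posterior → anterior, units mm), which removes the animal's position and
heading. Periodicity of the egocentric coordinates is summarized with a
Morlet continuous wavelet transform; the concatenated coordinates and
wavelet amplitudes are standardized and embedded in two dimensions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt

from .calibration import Calibration

logger = logging.getLogger(__name__)

REQUIRED_PARTS = ("abdomen_tip", "abdomen_center")
AEDES_PARTS = (
    "head",
    "proboscis_tip",
    "abdomen_center",
    "abdomen_tip",
    "leg_L1",
    "leg_L2",
    "leg_L3",
    "leg_R1",
    "leg_R2",
    "leg_R3",
)
ANOPHELES_PARTS = AEDES_PARTS + ("maxillary_palp_tip",)


@dataclass
class PoseTrack:
    """Per-frame body-part coordinates and likelihoods for one individual.

    ``df`` has a three-level column MultiIndex (scorer, bodypart, coord)
    with coord in {x, y, likelihood}; the index is the frame number.
    """

    df: pd.DataFrame
    fps: float = 25.0
    labels: np.ndarray | None = None  # optional per-frame behavior (synthetic)

    @property
    def parts(self) -> list[str]:
        return list(dict.fromkeys(self.df.columns.get_level_values(1)))

    @property
    def n_frames(self) -> int:
        return len(self.df)

    def xy(self, part: str) -> np.ndarray:
        scorer = self.df.columns[0][0]
        return self.df[scorer][part][["x", "y"]].to_numpy(float)

    def likelihood(self, part: str) -> np.ndarray:
        scorer = self.df.columns[0][0]
        return self.df[scorer][part]["likelihood"].to_numpy(float)

    def valid_mask(self, min_likelihood: float, parts=REQUIRED_PARTS) -> np.ndarray:
        ok = np.ones(self.n_frames, dtype=bool)
        for p in parts:
            ok &= self.likelihood(p) >= min_likelihood
        return ok

    def to_csv(self, path) -> None:
        self.df.round(6).to_csv(path, index_label="")

    @classmethod
    def from_arrays(
        cls,
        coords: dict[str, np.ndarray],
        likelihoods: dict[str, np.ndarray] | None = None,
        fps: float = 25.0,
        scorer: str = "bitetrack",
        labels: np.ndarray | None = None,
    ) -> "PoseTrack":
        cols, data = [], []
        for part, xy in coords.items():
            xy = np.asarray(xy, dtype=float)
            lk = (
                likelihoods[part]
                if likelihoods and part in likelihoods
                else np.ones(len(xy))
            )
            for coord, vals in (("x", xy[:, 0]), ("y", xy[:, 1]), ("likelihood", lk)):
                cols.append((scorer, part, coord))
                data.append(np.asarray(vals, dtype=float))
        df = pd.DataFrame(
            np.column_stack(data),
            columns=pd.MultiIndex.from_tuples(
                cols, names=["scorer", "bodyparts", "coords"]
            ),
        )
        return cls(df=df, fps=fps, labels=labels)


def read_pose_table(path, min_likelihood: float = 0.9, fps: float = 25.0):
    """Parse a three-header-row pose CSV.

    Returns (PoseTrack, valid) where ``valid`` flags frames whose required
    parts (abdominal tip and center) all reach ``min_likelihood``. Raises
    on a malformed header or missing required body parts.
    """
    try:
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    except (ValueError, IndexError) as e:
        raise ValueError(f"malformed pose table header: {e}") from e
    if df.columns.nlevels != 3:
        raise ValueError("malformed pose table: expected 3 header rows")
    df.columns = df.columns.set_names(["scorer", "bodyparts", "coords"])
    coords = set(df.columns.get_level_values(2))
    if not {"x", "y", "likelihood"} <= coords:
        raise ValueError(
            "malformed pose table: need x, y, likelihood per body part"
        )
    parts = set(df.columns.get_level_values(1))
    missing = [p for p in REQUIRED_PARTS if p not in parts]
    if missing:
        raise ValueError(f"missing required body-part columns: {missing}")
    track = PoseTrack(df=df.astype(float), fps=fps)
    return track, track.valid_mask(min_likelihood)


def _interpolate_gaps(arr: np.ndarray, valid: np.ndarray, max_gap: int) -> np.ndarray:
    """Linearly fill invalid runs of length <= max_gap; longer runs stay NaN."""
    out = arr.astype(float).copy()
    out[~valid] = np.nan
    n = len(out)
    idx = np.arange(n)
    for col in range(out.shape[1]) if out.ndim == 2 else [None]:
        v = out[:, col] if col is not None else out
        bad = np.isnan(v)
        if not bad.any() or bad.all():
            continue
        # fill short gaps only
        runs = []
        start = None
        for i in range(n):
            if bad[i] and start is None:
                start = i
            elif not bad[i] and start is not None:
                runs.append((start, i))
                start = None
        if start is not None:
            runs.append((start, n))
        fillable = np.zeros(n, dtype=bool)
        for s, e in runs:
            if e - s <= max_gap and s > 0 and e < n:
                fillable[s:e] = True
        good = ~bad
        filled = np.interp(idx, idx[good], v[good])
        v[fillable] = filled[fillable]
    return out


def egocentric_transform(
    track: PoseTrack,
    calibration: Calibration,
    min_likelihood: float = 0.9,
    max_gap: int = 5,
) -> pd.DataFrame:
    """Rigidly map image coordinates into the body frame, in mm.

    Origin at the abdominal tip, +x along tip → abdomen center. The map is
    translation + proper rotation + px→mm scale, so inter-part distances
    are preserved (in mm) and any rigid motion of the raw pose leaves the
    output unchanged. Frames whose required parts fall below
    ``min_likelihood`` are linearly interpolated if the gap is at most
    ``max_gap`` frames, otherwise left as NaN.

    Returns a DataFrame indexed by frame with (bodypart, x/y) columns.
    """
    valid = track.valid_mask(min_likelihood)
    tip = track.xy("abdomen_tip")
    cen = track.xy("abdomen_center")
    axis = cen - tip
    norm = np.hypot(axis[:, 0], axis[:, 1])
    if np.any((norm <= 1e-12) & valid):
        raise ValueError("degenerate body axis: abdomen tip equals abdomen center")
    with np.errstate(invalid="ignore", divide="ignore"):
        ex = axis / norm[:, None]
    # proper rotation: rows (ex, ey) with ey = ex rotated by +90 degrees
    cols = {}
    for part in track.parts:
        q = track.xy(part) - tip
        x_ego = q[:, 0] * ex[:, 0] + q[:, 1] * ex[:, 1]
        y_ego = -q[:, 0] * ex[:, 1] + q[:, 1] * ex[:, 0]
        xy = np.column_stack([x_ego, y_ego]) * calibration.mm_per_px
        xy = _interpolate_gaps(xy, valid, max_gap)
        cols[(part, "x")] = xy[:, 0]
        cols[(part, "y")] = xy[:, 1]
    out = pd.DataFrame(cols, index=track.df.index)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["bodyparts", "coords"])
    return out


@dataclass
class Spectrogram:
    """Morlet wavelet amplitudes of one egocentric coordinate."""

    frequencies: np.ndarray  # Hz
    times: np.ndarray  # s
    amplitudes: np.ndarray  # (n_freq, n_time), >= 0

    def save(self, path_base: str) -> None:
        """Dense array + JSON sidecar for the axes."""
        np.savetxt(f"{path_base}.txt", self.amplitudes)
        with open(f"{path_base}.json", "w") as fh:
            json.dump(
                {
                    "frequencies_hz": self.frequencies.tolist(),
                    "times_s": self.times.tolist(),
                },
                fh,
            )


def default_frequency_grid(fps: float, n: int = 25, f_min: float = 0.5) -> np.ndarray:
    return np.logspace(np.log10(f_min), np.log10(fps / 2.0), n)


def morlet_spectrogram(
    series,
    fps: float,
    freqs=None,
    wavelet: str = "cmor1.0-1.0",
) -> Spectrogram:
    """Continuous wavelet transform amplitude with a Morlet mother wavelet.

    The series mean is removed first; the default frequency grid is 25
    log-spaced channels between 0.5 Hz and the Nyquist frequency.
    """
    series = np.asarray(series, dtype=float)
    if len(series) < 2:
        raise ValueError("series must have at least 2 samples")
    freqs = default_frequency_grid(fps) if freqs is None else np.asarray(freqs, float)
    if np.any(freqs <= 0) or np.any(freqs > fps / 2.0 + 1e-9):
        raise ValueError("frequencies must lie in (0, fps/2]")
    scales = pywt.frequency2scale(wavelet, freqs / fps)
    coef, _ = pywt.cwt(series - series.mean(), scales, wavelet, sampling_period=1.0 / fps)
    return Spectrogram(
        frequencies=freqs,
        times=np.arange(len(series)) / fps,
        amplitudes=np.abs(coef),
    )


def assemble_features(ego: pd.DataFrame, spectrograms=None):
    """Concatenate egocentric coordinates and wavelet amplitudes per frame,
    standardize each feature to zero mean / unit variance, and drop
    zero-variance features (logged, not an error).

    Returns (matrix, names, keep_rows) where keep_rows flags frames
    without NaNs (long likelihood gaps).
    """
    blocks = [ego.to_numpy(float)]
    names = ["|".join(map(str, c)) for c in ego.columns]
    for k, spec in enumerate(spectrograms or []):
        blocks.append(spec.amplitudes.T)
        names += [f"cwt{k}_f{f:.3g}Hz" for f in spec.frequencies]
    x = np.column_stack(blocks)
    keep_rows = ~np.isnan(x).any(axis=1)
    x = x[keep_rows]
    sd = x.std(axis=0)
    # constant up to float rounding counts as zero variance: standardizing
    # such a column would only amplify numerical noise
    zero = sd <= 1e-9 * (1.0 + np.abs(x.mean(axis=0)))
    if zero.any():
        logger.info(
            "dropping %d zero-variance features: %s",
            int(zero.sum()),
            [n for n, z in zip(names, zero) if z][:10],
        )
    x = x[:, ~zero]
    names = [n for n, z in zip(names, zero) if not z]
    x = (x - x.mean(axis=0)) / x.std(axis=0)
    return x, names, keep_rows


def assemble_and_embed(
    ego: pd.DataFrame,
    spectrograms=None,
    seed: int = 0,
    method: str = "tsne",
    perplexity: float = 30.0,
) -> np.ndarray:
    """Standardized pose + wavelet features embedded in two dimensions.

    The embedder is pluggable ("tsne" or "pca"); the contract is the
    feature assembly and scaling. Returns (n_frames, 2), seeded.
    """
    x, _, keep = assemble_features(ego, spectrograms)
    if len(x) < 10:
        raise ValueError("need at least 10 frames to embed")
    if method == "tsne":
        from sklearn.manifold import TSNE

        emb = TSNE(
            n_components=2,
            random_state=int(seed),
            perplexity=min(perplexity, (len(x) - 1) / 3.0),
            init="pca",
        ).fit_transform(x)
    elif method == "pca":
        from sklearn.decomposition import PCA

        emb = PCA(n_components=2, random_state=int(seed)).fit_transform(x)
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    out = np.full((len(keep), 2), np.nan)
    out[keep] = emb
    return out
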