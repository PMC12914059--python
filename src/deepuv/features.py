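"""Per-cell morphological, texture and fractal features from static frames.

Feature set: area (px^2 and um^2), circularity, equivalent diameter,
eccentricity, intensity statistics (mean, std, Shannon entropy, skewness,
kurtosis) over mask pixels, and a box-counting fractal dimension per each
of eight equal background-corrected intensity bins.  Features are ranked
by chi-square tests against class labels and embedded in 2-D with UMAP for
visualization.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from skimage import measure
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .segment import CellCrop

N_FRACTAL_BINS = 8
ENTROPY_BINS = 64
BOX_SIZES = (2, 4, 8, 16, 32)

FRACTAL_COLUMNS = [f"fractal_{k}" for k in range(1, N_FRACTAL_BINS + 1)]
STATIC_COLUMNS = [
    "area_px", "area_um2", "circularity", "equivalent_diameter",
    "eccentricity", "mean_attenuation", "std_attenuation", "entropy",
    "skewness", "kurtosis", *FRACTAL_COLUMNS,
]


def fractal_bins():
    """The eight equal intensity intervals [(k-1)/8, k/8); bin 8 closed at 1."""
    edges = np.arange(N_FRACTAL_BINS + 1) / N_FRACTAL_BINS
    return [(edges[k], edges[k + 1]) for k in range(N_FRACTAL_BINS)]


def box_counting_dimension(mask: np.ndarray, sizes=BOX_SIZES) -> float:
    """Box-counting fractal dimension of a binary mask.

    Counts occupied boxes at each grid size and returns the least-squares
    slope of log(count) against log(1/size); an empty mask returns 0 by
    convention, and a filled 2-D region approaches 2.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return 0.0
    counts = []
    for s in sizes:
        h = int(np.ceil(mask.shape[0] / s)) * s
        w = int(np.ceil(mask.shape[1] / s)) * s
        padded = np.zeros((h, w), dtype=bool)
        padded[: mask.shape[0], : mask.shape[1]] = mask
        boxes = padded.reshape(h // s, s, w // s, s).any(axis=(1, 3))
        counts.append(max(boxes.sum(), 1))
    slope = np.polyfit(np.log(1.0 / np.asarray(sizes, dtype=float)), np.log(counts), 1)[0]
    return float(slope)


def fractal_features(crop: CellCrop | np.ndarray) -> np.ndarray:
    """Box-counting dimension of the per-bin binary masks of a cell crop.

    Pixel k of the cell belongs to the bin containing its background-
    corrected intensity; the eight masks are pairwise disjoint and cover
    the cell.  Empty bins score 0.
    """
    image = crop.image if isinstance(crop, CellCrop) else np.asarray(crop, dtype=float)
    cell = image > 0
    dims = np.zeros(N_FRACTAL_BINS)
    for k, (lo, hi) in enumerate(fractal_bins()):
        if k == N_FRACTAL_BINS - 1:
            sel = cell & (image >= lo) & (image <= hi)
        else:
            sel = cell & (image >= lo) & (image < hi)
        dims[k] = box_counting_dimension(sel)
    return dims


def shannon_entropy(values: np.ndarray, bins: int = ENTROPY_BINS) -> float:
    """Shannon entropy (bits) of a ``bins``-bin histogram over [0, 1]."""
    hist, _ = np.histogram(values, bins=bins, range=(0.0, 1.0))
    p = hist / hist.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def static_features(crop: CellCrop | np.ndarray, pixel_size: float = 1.0,
                    min_area: int = 5) -> pd.Series:
    """One feature-table row for a zero-padded cell crop.

    ``circularity = 4 pi A / P^2``; ``equivalent_diameter = 2 sqrt(A/pi)``;
    intensity statistics are computed over mask pixels only.  Crops with
    fewer than ``min_area`` pixels are flagged invalid (all-NaN features).
    """
    image = crop.image if isinstance(crop, CellCrop) else np.asarray(crop, dtype=float)
    mask = image > 0
    area = int(mask.sum())
    row = pd.Series(np.nan, index=STATIC_COLUMNS + ["valid"], dtype=float)
    if area < min_area:
        row["valid"] = 0.0
        return row
    props = measure.regionprops(mask.astype(np.uint8), intensity_image=image)[0]
    perimeter = max(props.perimeter, 1e-9)
    vals = image[mask]
    row["area_px"] = float(area)
    row["area_um2"] = float(area) * pixel_size ** 2
    row["circularity"] = float(4 * np.pi * area / perimeter ** 2)
    row["equivalent_diameter"] = float(2 * np.sqrt(area / np.pi))
    row["eccentricity"] = float(props.eccentricity)
    row["mean_attenuation"] = float(vals.mean())
    row["std_attenuation"] = float(vals.std())
    row["entropy"] = shannon_entropy(vals)
    row["skewness"] = float(stats.skew(vals)) if area > 2 else 0.0
    row["kurtosis"] = float(stats.kurtosis(vals)) if area > 3 else 0.0
    row[FRACTAL_COLUMNS] = fractal_features(image)
    row["valid"] = 1.0
    return row


def feature_table(crops, pixel_size: float = 1.0, labels=None) -> pd.DataFrame:
    """Stack :func:`static_features` rows for a sequence of crops."""
    rows = [static_features(c, pixel_size=pixel_size) for c in crops]
    table = pd.DataFrame(rows).reset_index(drop=True)
    if labels is not None:
        table["label"] = list(labels)
    return table


class Chi2FeatureRanker(BaseEstimator):
    """Rank features by chi-square association with class labels.

    Continuous features are discretized into ``n_bins`` quantile bins and
    each feature's bin-by-class contingency table is scored with Pearson's
    chi-square statistic; features are ranked by descending score.

    Attributes
    ----------
    scores_ : ndarray of chi-square statistics per feature
    ranking_ : feature names in descending score order
    """

    def __init__(self, n_bins: int = 10):
        self.n_bins = n_bins

    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("chi-square ranking requires >= 2 classes")
        X = pd.DataFrame(X)
        scores = {}
        for col in X.columns:
            v = X[col].to_numpy(dtype=float)
            ok = np.isfinite(v)
            if ok.sum() < 2 or np.ptp(v[ok]) == 0:
                scores[col] = 0.0
                continue
            edges = np.unique(np.quantile(v[ok], np.linspace(0, 1, self.n_bins + 1)))
            binned = np.digitize(v[ok], edges[1:-1])
            tab = pd.crosstab(binned, y[ok]).to_numpy()
            if min(tab.shape) < 2:
                scores[col] = 0.0
                continue
            chi2 = stats.chi2_contingency(tab, correction=False)[0]
            scores[col] = float(chi2)
        self.feature_names_ = list(X.columns)
        self.scores_ = np.array([scores[c] for c in X.columns])
        order = np.argsort(-self.scores_, kind="stable")
        self.ranking_ = [self.feature_names_[i] for i in order]
        return self

    def top(self, k: int) -> list[str]:
        check_is_fitted(self, "ranking_")
        return self.ranking_[:k]


def rank_features_chi2(table: pd.DataFrame, labels, n_bins: int = 10) -> pd.DataFrame:
    """Convenience wrapper over :class:`Chi2FeatureRanker`.

    Returns a DataFrame with columns ``feature`` and ``score`` sorted by
    descending chi-square score.  The top 12 features are the conventional
    display set for the 3-class problem, the top 8 for subtyping.
    """
    ranker = Chi2FeatureRanker(n_bins=n_bins).fit(table, labels)
    order = np.argsort(-ranker.scores_, kind="stable")
    return pd.DataFrame(
        {"feature": [ranker.feature_names_[i] for i in order],
         "score": ranker.scores_[order]}
    )


def class_zscore_profile(table: pd.DataFrame, labels, features=None) -> pd.DataFrame:
    """Mean per-class z-score of each feature (clustergram-style summary)."""
    X = table[features] if features is not None else table
    z = (X - X.mean()) / X.std(ddof=0).replace(0, 1)
    z["__label"] = np.asarray(labels)
    return z.groupby("__label").mean()


def embed_2d(table: pd.DataFrame, seed: int = 0, n_neighbors: int = 15,
             min_dist: float = 0.1) -> np.ndarray:
    """2-D UMAP embedding of z-scored features (n_neighbors=15, min_dist=0.1).

    Deterministic for a fixed seed; requires at least 16 cells.
    """
    X = pd.DataFrame(table).to_numpy(dtype=float)
    if X.shape[0] < 16:
        raise ValueError("embedding requires >= 16 cells")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xz = (X - mu) / sd
    import umap

    reducer = umap.UMAP(n_neighbors=n_neighbors, min_dist=min_dist,
                        n_components=2, random_state=seed)
    coords = reducer.fit_transform(Xz)
    if not np.all(np.isfinite(coords)):
        raise RuntimeError("embedding produced non-finite coordinates")
    return coords
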