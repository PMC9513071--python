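"""Align, reduce and cluster receptive fields into functional types.

The pipeline mirrors standard practice for typing neurons by their RFs:

1. ``align_centers`` -- hierarchical pre-clustering of the (noisy) RFs within
   a field (correlation distance, average linkage, fixed distance criterion
   0.05); each pre-cluster's mean RF defines a common center (its extremum,
   maximum for On / minimum for Off) to which every member is shifted.
2. ``crop_half`` -- one spatial half of the aligned RF (center to edge) over
   the full lag span, flattened, since off-center stimulation leaves only one
   half reliably sampled in real recordings.
3. ``fit_cluster_model`` -- sparse PCA (4 components) on the flattened
   vectors, optionally augmented with IPL depth, followed by Gaussian-mixture
   clustering with the number of clusters chosen by BIC over a candidate
   range (default 3..19).
4. ``stratification_correlation`` -- Pearson correlation between cluster
   depth-density profiles (Gaussian KDE over IPL depth) and reference
   (anatomical) stratification profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.decomposition import SparsePCA
from sklearn.mixture import GaussianMixture
from sklearn.preprocessing import StandardScaler

from .errors import (
    FeatureMismatchError,
    InsufficientDataError,
    InvalidParameterError,
    UndefinedCorrelationError,
)
from .rf import SpaceTimeRF

__all__ = [
    "ClusterModel",
    "StratificationProfile",
    "align_centers",
    "crop_half",
    "crop_half_population",
    "fit_cluster_model",
    "predict_cluster",
    "kde_profile",
    "stratification_correlation",
    "match_types",
]


@dataclass
class StratificationProfile:
    """Normalized density of terminals over IPL depth in [0, 1]."""

    depth_grid: np.ndarray
    density: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.depth_grid = np.asarray(self.depth_grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if np.any(self.density < 0):
            raise InvalidParameterError("density must be non-negative")
        area = np.trapezoid(self.density, self.depth_grid)
        if area > 0:
            self.density = self.density / area


@dataclass
class ClusterModel:
    """Fitted sparse-PCA basis + Gaussian mixture + chosen cluster count."""

    spca: SparsePCA
    scaler: StandardScaler
    gmm: GaussianMixture
    k_selected: int
    bic_curve: dict
    depth_included: bool
    labels_: np.ndarray

    @property
    def n_components(self) -> int:
        return self.spca.n_components


def align_centers(
    rfs: list,
    link_threshold: float = 0.05,
    metric: str = "correlation",
    linkage_method: str = "average",
) -> list:
    """Center-align RFs via hierarchical pre-clustering.

    RFs are pre-clustered on their flattened weights with a fixed distance
    criterion; per pre-cluster, the center is the spatial position of the
    extremum of the mean RF (max for On, min for Off majority), and each
    member is shifted (zero-filled) so centers coincide with the grid middle.
    Singleton pre-clusters are allowed; a single RF is returned re-centered.
    """
    if len(rfs) == 0:
        raise InvalidParameterError("need at least one RF")
    flat = np.stack([rf.weights.ravel() for rf in rfs])
    if len(rfs) == 1:
        groups = np.array([1])
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant rows give corr warnings
            z = hierarchy.linkage(flat, method=linkage_method, metric=metric)
        z = np.nan_to_num(z, nan=1.0)
        groups = hierarchy.fcluster(z, t=link_threshold, criterion="distance")
    out = [None] * len(rfs)
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        mean_w = np.mean([rfs[i].weights for i in idx], axis=0)
        pols = [rfs[i].polarity for i in idx]
        pol = +1 if sum(pols) >= 0 else -1
        if pol == +1:
            ci = int(np.unravel_index(np.argmax(mean_w), mean_w.shape)[0])
        else:
            ci = int(np.unravel_index(np.argmin(mean_w), mean_w.shape)[0])
        for i in idx:
            rf = rfs[i]
            mid = rf.n_space // 2
            shift = mid - ci
            w = np.zeros_like(rf.weights)
            if shift >= 0:
                w[shift:, :] = rf.weights[: rf.n_space - shift, :]
            else:
                w[:shift, :] = rf.weights[-shift:, :]
            center = rf.origin_um + (mid + 0.5) * rf.dx
            out[i] = rf.copy(weights=w, center_um=center)
    return out


def crop_half(
    rf: SpaceTimeRF, side: str = "right", width_bins: int | None = None
) -> np.ndarray:
    """One spatial half of an aligned RF (center to edge), flattened.

    The vector runs from the center bin outward over the full lag span, so
    for a spatially symmetric RF the 'left' and 'right' vectors coincide.
    ``width_bins`` crops to a common width across ROIs.
    """
    ci = int(round((rf.center_um - rf.origin_um) / rf.dx - 0.5))
    if not (0 <= ci < rf.n_space):
        raise InvalidParameterError("RF center lies outside its spatial extent")
    if side == "right":
        half = rf.weights[ci:, :]
    elif side == "left":
        half = rf.weights[: ci + 1, :][::-1, :]
    else:
        raise InvalidParameterError("side must be 'left' or 'right'")
    if width_bins is not None:
        if width_bins < 1 or width_bins > half.shape[0]:
            raise InvalidParameterError("width_bins exceeds the available half")
        half = half[:width_bins, :]
    return half.ravel()


def crop_half_population(rfs: list, side: str = "right") -> np.ndarray:
    """Crop all RFs to the half width available for every ROI; stack vectors."""
    widths = []
    for rf in rfs:
        ci = int(round((rf.center_um - rf.origin_um) / rf.dx - 0.5))
        widths.append(rf.n_space - ci if side == "right" else ci + 1)
    w = max(1, min(widths))
    return np.stack([crop_half(rf, side=side, width_bins=w) for rf in rfs])


def fit_cluster_model(
    vectors: np.ndarray,
    depths: np.ndarray | None = None,
    n_components: int = 4,
    k_range=range(3, 20),
    seed: int = 0,
    covariance_type: str = "full",
    n_init: int = 3,
) -> ClusterModel:
    """Sparse PCA + Gaussian-mixture clustering with BIC model selection.

    Feature set: sparse-PCA component weights of the flattened RF vectors,
    plus (optionally) the ROI's IPL depth; features are jointly standardized
    so no single one dominates.  For each candidate k a mixture is fitted
    (k-means++ initialization, ``n_init`` restarts) and the k minimizing the
    Bayesian information criterion is selected.  Deterministic under ``seed``.
    """
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 2:
        raise InvalidParameterError("vectors must be 2-D (n_samples, n_features)")
    n = vectors.shape[0]
    ks = [int(k) for k in k_range]
    if not ks:
        raise InvalidParameterError("k_range must be non-empty")
    if n < min(ks):
        raise InsufficientDataError("fewer samples than the smallest cluster count")
    spca = SparsePCA(n_components=n_components, random_state=seed)
    scores = spca.fit_transform(vectors)
    feats = scores
    depth_included = depths is not None
    if depth_included:
        depths = np.asarray(depths, dtype=float).reshape(-1, 1)
        if len(depths) != n:
            raise InvalidParameterError("depths length must match vectors")
        feats = np.hstack([scores, depths])
    scaler = StandardScaler()
    feats = scaler.fit_transform(feats)

    bic_curve: dict[int, float] = {}
    best = None
    for k in ks:
        if k > n:
            warnings.warn(f"skipping k={k}: more clusters than samples")
            continue
        gmm = GaussianMixture(
            n_components=k,
            covariance_type=covariance_type,
            n_init=n_init,
            init_params="k-means++",
            random_state=seed,
            reg_covar=1e-5,
        ).fit(feats)
        bic = float(gmm.bic(feats))
        bic_curve[k] = bic
        if best is None or bic < best[0]:
            best = (bic, k, gmm)
    _, k_sel, gmm = best
    return ClusterModel(
        spca=spca,
        scaler=scaler,
        gmm=gmm,
        k_selected=k_sel,
        bic_curve=bic_curve,
        depth_included=depth_included,
        labels_=gmm.predict(feats),
    )


def _model_features(model: ClusterModel, vectors: np.ndarray, depths) -> np.ndarray:
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    try:
        scores = model.spca.transform(vectors)
    except ValueError as e:
        raise FeatureMismatchError(str(e)) from e
    if model.depth_included:
        if depths is None:
            raise FeatureMismatchError("model was fitted with depth; provide depths")
        depths = np.asarray(depths, dtype=float).reshape(-1, 1)
        scores = np.hstack([scores, depths])
    return model.scaler.transform(scores)


def predict_cluster(
    model: ClusterModel, vectors: np.ndarray, depths=None
) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-posterior cluster assignment plus posterior probabilities.

    Used to carry control-condition cluster labels over to data recorded
    under drug conditions.
    """
    feats = _model_features(model, vectors, depths)
    return model.gmm.predict(feats), model.gmm.predict_proba(feats)


def kde_profile(
    depths, label: str = "", grid: np.ndarray | None = None, bw_method=None
) -> StratificationProfile:
    """Gaussian-KDE density of IPL depths on a common [0, 1] grid."""
    depths = np.asarray(depths, dtype=float)
    if grid is None:
        grid = np.linspace(0.0, 1.0, 101)
    if len(depths) < 2 or np.std(depths) == 0:
        # degenerate band: narrow Gaussian bump at the (single) depth
        mu = float(np.mean(depths))
        dens = np.exp(-0.5 * ((grid - mu) / 0.02) ** 2)
    else:
        dens = stats.gaussian_kde(depths, bw_method=bw_method)(grid)
    return StratificationProfile(grid, dens, label=label)


def stratification_correlation(
    cluster_profiles: list, reference_profiles: list
) -> pd.DataFrame:
    """Pearson correlation between cluster and reference stratification profiles.

    Profiles must share a depth grid; returns a (clusters x references)
    correlation matrix.
    """
    if not cluster_profiles or not reference_profiles:
        raise InvalidParameterError("profile lists must be non-empty")
    grid = cluster_profiles[0].depth_grid
    for p in list(cluster_profiles) + list(reference_profiles):
        if len(p.depth_grid) != len(grid) or not np.allclose(p.depth_grid, grid):
            raise InvalidParameterError("profiles must share a common depth grid")
        if np.std(p.density) == 0:
            raise UndefinedCorrelationError(
                f"profile {p.label!r} has zero variance"
            )
    mat = np.empty((len(cluster_profiles), len(reference_profiles)))
    for i, cp in enumerate(cluster_profiles):
        for j, rp in enumerate(reference_profiles):
            mat[i, j] = stats.pearsonr(cp.density, rp.density)[0]
    return pd.DataFrame(
        mat,
        index=[p.label for p in cluster_profiles],
        columns=[p.label for p in reference_profiles],
    )


def match_types(corr: pd.DataFrame, threshold: float = 0.7) -> dict:
    """Best-matching reference type per cluster, where correlation >= threshold."""
    out = {}
    for label, row in corr.iterrows():
        j = row.idxmax()
        out[label] = j if row[j] >= threshold else None
    return out
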