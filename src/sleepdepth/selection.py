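"""Choosing the scaling exponent and PCA component subset.

The best-separating representation is found by a grid search: for each
candidate gamma, spectral vectors are recomputed, a PCA is refitted, and the
GDV of the sleep-stage clusters is evaluated for every single component and
every component pair.  The cell with the most negative GDV wins.  As a
cross-check, the component whose GDV is best should also be the one whose
score correlates best (in modulus) with the numeric hypnogram.

Also provided: stage-conditional score distributions (the "fuzziness" view of
the stages) and per-recording hypnogram correlations under a globally fitted
versus a per-recording ("local") PCA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .depth import (
    DepthSeries,
    Hypnogram,
    depth_hypnogram_correlation,
    fit_spectral_pca,
    project,
)
from .gdv import LabeledPointSet, gdv
from .spectra import (
    EpochedRecording,
    Recording,
    SpectralVectors,
    preprocess,
    spectral_vectors,
)

__all__ = [
    "SelectionGrid",
    "gdv_component_matrix",
    "correlation_matrix",
    "stage_conditional_distributions",
    "select_gamma_component",
    "per_recording_correlation",
    "mds_embedding",
]


@dataclass
class SelectionGrid:
    """Grid-search result over scaling exponents and component subsets.

    ``gdv_matrices[gamma]`` is symmetric over the component pool; its diagonal
    holds single-component GDVs.  ``corr_matrices[gamma]`` is a |Pearson|
    matrix over the components plus a ``hyp`` row/column.  ``best`` is the
    (gamma, component subset) pair with the most negative GDV.
    """

    gammas: tuple
    component_pool: tuple
    gdv_matrices: dict
    corr_matrices: dict
    best: tuple

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table: gamma, comp_i, comp_j, gdv."""
        rows = []
        pool = self.component_pool
        for g in self.gammas:
            m = self.gdv_matrices[g]
            for a, ci in enumerate(pool):
                for b, cj in enumerate(pool[a:], start=a):
                    rows.append(
                        {"gamma": g, "comp_i": ci, "comp_j": cj, "gdv": m[a, b]}
                    )
        return pd.DataFrame(rows)


def gdv_component_matrix(
    scores: np.ndarray, labels: Sequence, pool: Sequence[int] = (0, 1, 2)
) -> np.ndarray:
    """Symmetric GDV matrix over component pairs; diagonal = single components."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pool = tuple(pool)
    m = np.empty((len(pool), len(pool)))
    for a, ci in enumerate(pool):
        m[a, a] = gdv(LabeledPointSet(scores[:, [ci]], labels))
        for b in range(a + 1, len(pool)):
            cj = pool[b]
            val = gdv(LabeledPointSet(scores[:, [ci, cj]], labels))
            m[a, b] = m[b, a] = val
    return m


def correlation_matrix(
    scores: np.ndarray, hyp: Hypnogram | np.ndarray, pool: Sequence[int] = (0, 1, 2)
) -> pd.DataFrame:
    """|Pearson| among component scores and between each and the hypnogram.

    Returns a DataFrame whose first row/column (``hyp``) holds the hypnogram
    correlations; component-vs-component entries are near zero by PCA
    construction on the training data.
    """
    scores = np.asarray(scores, dtype=float)
    numeric = hyp.numeric if isinstance(hyp, Hypnogram) else np.asarray(hyp, float)
    pool = tuple(pool)
    cols = [numeric] + [scores[:, c] for c in pool]
    names = ["hyp"] + [f"C{c}" for c in pool]
    stacked = np.column_stack(cols)
    if np.any(stacked.std(axis=0) == 0):
        raise ValueError("correlation undefined for a constant series")
    corr = np.abs(np.corrcoef(stacked, rowvar=False))
    return pd.DataFrame(corr, index=names, columns=names)


def stage_conditional_distributions(
    scores: np.ndarray,
    labels: Sequence,
    component: int,
    bins: int = 60,
) -> tuple[np.ndarray, Mapping[str, np.ndarray]]:
    """Per-stage normalized histograms of one component's scores.

    All stages share one equal-width bin grid spanning the pooled score range;
    each histogram sums to 1.  Returns (bin_edges, {stage: histogram}).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.size == 0:
        raise ValueError("empty score matrix")
    x = scores[:, component]
    edges = np.histogram_bin_edges(x, bins=bins)
    out = {}
    for stage in np.unique(labels):
        vals = x[labels == stage]
        hist, _ = np.histogram(vals, bins=edges)
        out[str(stage)] = hist / hist.sum()
    return edges, out


def mds_embedding(
    points: np.ndarray,
    labels: Sequence,
    per_stage: int = 300,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """2-D multidimensional-scaling embedding for qualitative cluster plots.

    Purely a visualization hook (delegates to scikit-learn's metric MDS, which
    preserves all mutual distances): each stage is subsampled to at most
    ``per_stage`` points (default 300, i.e. 1500 points over five stages)
    before embedding.  Returns (embedded N x 2 coordinates, matching labels).
    """
    from sklearn.manifold import MDS

    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    rows = _subsample_per_stage(labels, per_stage, seed)
    coords = MDS(
        n_components=2, random_state=seed, n_init=1, normalized_stress="auto"
    ).fit_transform(points[rows])
    return coords, labels[rows]


def _pool_spectra(
    recordings: Sequence[EpochedRecording], gamma: float, f_max: float
) -> tuple[SpectralVectors, np.ndarray]:
    svs = [spectral_vectors(er, gamma=gamma, f_max=f_max) for er in recordings]
    values = np.vstack([sv.values for sv in svs])
    pooled = SpectralVectors(
        values,
        gamma=gamma,
        freq_resolution=svs[0].freq_resolution,
        bin_indices=svs[0].bin_indices,
    )
    labels = np.concatenate([er.labels for er in recordings])
    return pooled, labels


def _subsample_per_stage(
    labels: np.ndarray, max_per_stage: int, seed: int
) -> np.ndarray:
    rng = np.random.default_rng(seed)
    keep = []
    for stage in np.unique(labels):
        rows = np.flatnonzero(labels == stage)
        if rows.size > max_per_stage:
            rows = rng.choice(rows, size=max_per_stage, replace=False)
        keep.append(rows)
    return np.sort(np.concatenate(keep))


def select_gamma_component(
    recordings: Sequence[EpochedRecording],
    gammas: Sequence[float] = (1.0, 0.7, 0.5),
    component_pool: Sequence[int] = (0, 1, 2),
    f_max: float = 35.0,
    max_epochs_per_stage: int | None = None,
    subsample_seed: int = 0,
) -> SelectionGrid:
    """Grid search over scaling exponents and PCA component subsets.

    Every recording must be preprocessed (artifact-free, z-scored) and carry
    stage labels.  For each gamma the spectral vectors are recomputed and the
    PCA refitted.  ``max_epochs_per_stage`` optionally subsamples the pooled
    epochs (per stage, seeded) before the O(K^2) GDV evaluation.
    Deterministic given its inputs.
    """
    gammas = tuple(gammas)
    component_pool = tuple(component_pool)
    if not gammas or not component_pool:
        raise ValueError("empty selection grid")
    n_components = max(component_pool) + 1
    gdv_matrices: dict = {}
    corr_matrices: dict = {}
    best = None
    best_val = np.inf
    for g in gammas:
        pooled, labels = _pool_spectra(recordings, g, f_max)
        model = fit_spectral_pca(pooled, n_components=n_components)
        scores = project(model, pooled)
        if max_epochs_per_stage is not None:
            rows = _subsample_per_stage(labels, max_epochs_per_stage, subsample_seed)
            scores_g, labels_g = scores[rows], labels[rows]
        else:
            scores_g, labels_g = scores, labels
        m = gdv_component_matrix(scores_g, labels_g, component_pool)
        gdv_matrices[g] = m
        numeric = np.array(
            [Hypnogram(labels_g).numeric], dtype=float
        ).ravel()
        corr_matrices[g] = correlation_matrix(scores_g, numeric, component_pool)
        for a, ci in enumerate(component_pool):
            for b in range(a, len(component_pool)):
                subset = (ci,) if a == b else (ci, component_pool[b])
                if m[a, b] < best_val:
                    best_val = m[a, b]
                    best = (g, subset)
    return SelectionGrid(
        gammas=gammas,
        component_pool=component_pool,
        gdv_matrices=gdv_matrices,
        corr_matrices=corr_matrices,
        best=best,
    )


def per_recording_correlation(
    cohort: Sequence[tuple[Recording, Hypnogram]],
    mode: str = "global",
    gamma: float = 0.5,
    f_max: float = 35.0,
    n_components: int = 3,
    component: int = 1,
) -> np.ndarray:
    """|Pearson(C1, hypnogram)| for each recording of a cohort.

    ``global`` mode fits one PCA on the pooled spectra of all recordings;
    ``local`` refits per recording.  Per-recording failures (e.g. a constant
    hypnogram) yield NaN rather than aborting the cohort.
    """
    if mode not in ("global", "local"):
        raise ValueError("mode must be 'global' or 'local'")
    prepared = [
        (preprocess(rec, labels=hyp.stages), hyp) for rec, hyp in cohort
    ]
    svs = [spectral_vectors(er, gamma=gamma, f_max=f_max) for er, _ in prepared]
    if mode == "global":
        pooled = SpectralVectors(
            np.vstack([sv.values for sv in svs]),
            gamma=gamma,
            freq_resolution=svs[0].freq_resolution,
            bin_indices=svs[0].bin_indices,
        )
        model = fit_spectral_pca(pooled, n_components=n_components)
        models = [model] * len(prepared)
    else:
        models = [fit_spectral_pca(sv, n_components=n_components) for sv in svs]
    out = np.empty(len(prepared))
    for i, ((er, hyp), sv, model) in enumerate(zip(prepared, svs, models)):
        try:
            ds = DepthSeries(
                project(model, sv)[:, component], epoch_indices=er.epoch_indices
            )
            out[i] = depth_hypnogram_correlation(ds, hyp)
        except ValueError:
            out[i] = np.nan
    return out
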