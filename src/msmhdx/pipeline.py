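"""High-level orchestration: the end-to-end analysis chain and the
iterative sample-expand loop.

``analyze_ensemble`` runs featurize -> IVAC -> k-means -> MSM -> PCCA ->
frame weights in one call. ``iterative_ivac_sampling`` mirrors the adaptive
sampling procedure: fit IVAC on the cumulative data set, project, select
poorly sampled structures, and start new trajectories from them — with
"run new simulation" realised by the synthetic generator seeded from the
hidden states of the selected frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ivac import TICModel, fit_ivac, project, select_seeds, spectral_gap
from .msm import (
    MarkovModel,
    MicrostateModel,
    estimate_msm,
    frame_weights,
    kmeans_cluster,
)
from .pcca import MacroClustering, pcca
from .synthetic import GroundTruth, HiddenStateSpec, generate_ensemble
from .trajectory import FeatureMatrix, TrajectoryEnsemble, pairwise_ca_distances

__all__ = ["EnsembleAnalysis", "analyze_ensemble", "iterative_ivac_sampling"]


@dataclass
class EnsembleAnalysis:
    """All intermediate artifacts of one pipeline run."""

    features: FeatureMatrix
    tic_model: TICModel
    n_components: int
    projection: np.ndarray
    micro: MicrostateModel
    msm: MarkovModel
    clustering: MacroClustering
    frame_weights: np.ndarray

    def frame_macro_labels(self) -> np.ndarray:
        """Macro-cluster label per frame (-1 for frames outside the model)."""
        labels = self.micro.concatenated()
        smap = self.msm.state_map(max(len(self.msm.count_matrix), labels.max() + 1))
        out = np.full(len(labels), -1, dtype=np.int64)
        inside = smap[labels] >= 0
        out[inside] = self.clustering.crisp_labels[smap[labels[inside]]]
        return out


def analyze_ensemble(
    ensemble: TrajectoryEnsemble,
    lag_min: int,
    lag_max: int,
    k: int = 1000,
    msm_lag: int | None = None,
    m: int = 10,
    n_components: int | None = None,
    residue_selection=None,
    mode: str = "symmetrized",
    seed: int = 0,
) -> EnsembleAnalysis:
    """Featurize, reduce, discretize, estimate and coarse-grain in one call.

    Lags are in frames. ``n_components=None`` retains the tICs before the
    spectral gap (at least 1). ``msm_lag`` defaults to ``lag_max``.
    """
    features = pairwise_ca_distances(ensemble, residue_selection)
    tic = fit_ivac(features, lag_min, lag_max)
    if n_components is None:
        try:
            n_components = spectral_gap(tic.eigenvalues)
        except ValueError:
            n_components = min(3, tic.n_features)
    proj = project(tic, features, n_components)
    blocks, start = [], 0
    for n in features.traj_lengths:
        blocks.append(proj[start : start + n])
        start += n
    micro = kmeans_cluster(blocks, k=k, seed=seed)
    msm = estimate_msm(micro.assignments, msm_lag or lag_max, mode=mode)
    clustering = pcca(msm, m)
    w = frame_weights(msm, micro.assignments)
    return EnsembleAnalysis(
        features=features,
        tic_model=tic,
        n_components=n_components,
        projection=proj,
        micro=micro,
        msm=msm,
        clustering=clustering,
        frame_weights=w,
    )


def iterative_ivac_sampling(
    spec: HiddenStateSpec,
    n_rounds: int = 3,
    n_traj_initial: int = 5,
    n_traj_per_round: int = 2,
    n_frames: int = 2000,
    lag_min: int = 1,
    lag_max: int = 20,
    n_components: int = 3,
    seed: int = 0,
) -> tuple[TrajectoryEnsemble, GroundTruth, TICModel]:
    """Adaptive sampling loop on the synthetic generator.

    Round 0 samples ``n_traj_initial`` stationary-start trajectories. Each
    further round fits IVAC on the cumulative data, projects it, picks the
    ``n_traj_per_round`` lowest-density frames in tIC space, and starts new
    trajectories from the hidden states underlying those frames. Returns the
    cumulative ensemble, the matching ground truth, and the final model.
    """
    ensemble, truth = generate_ensemble(spec, n_traj_initial, n_frames, seed)
    tic = None
    for r in range(1, n_rounds):
        features = pairwise_ca_distances(ensemble)
        tic = fit_ivac(features, lag_min, lag_max)
        proj = project(tic, features, min(n_components, tic.n_features))
        picks = select_seeds(proj, n_seeds=n_traj_per_round, seed=seed + r)
        states = truth.concatenated_states()[picks]
        new_ens, new_truth = generate_ensemble(
            spec,
            n_traj_per_round,
            n_frames,
            seed=seed + 1000 * r,
            initial_states=states,
        )
        ensemble = TrajectoryEnsemble(
            spec.topology,
            ensemble.trajectories + new_ens.trajectories,
            frame_interval=spec.frame_interval,
        )
        truth = GroundTruth(
            state_sequences=truth.state_sequences + new_truth.state_sequences,
            true_populations=truth.true_populations,
            true_timescales=truth.true_timescales,
            true_hb_pattern=truth.true_hb_pattern,
        )
    features = pairwise_ca_distances(ensemble)
    tic = fit_ivac(features, lag_min, lag_max)
    return ensemble, truth, tic
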