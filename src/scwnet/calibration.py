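"""λ calibration, curve-agreement metrics and PCA-based representative
selection.

The weight λ of the hydrogen thermal-energy term is phenomenological; it is
calibrated by scanning a grid, building networks for every frame at each λ,
pooling the connected-component size counts, and minimising the mean
absolute error between the pooled size fractions and a reference
distribution (e.g. an experimentally derived cluster-size distribution).

Representative frames of a trajectory are picked by flattening each frame
to its site-coordinate vector (4 sites × 3 coordinates × N molecules),
running a PCA across frames, and taking the frames closest to the mean in
the reduced space; representative connected components of a size/topology
class are picked the same way in a four-descriptor space (sum and spread of
bond lengths, mean and spread of edge energies).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .energetics import CriterionParameters
from .model_io import DEFAULT_FF, ForceFieldParameters, Frame
from .network_build import InteractionNetwork, geometric_pair_table
from .topology import component_size_distribution, connected_components

logger = logging.getLogger(__name__)


@dataclass
class AgreementMetrics:
    """Pointwise agreement of a predicted curve with an observed one."""

    r_squared: float
    rmse: float
    mae: float


@dataclass
class CalibrationResult:
    """λ grid scan against a reference size distribution.

    ``lambda_star`` minimises the MAE over the grid (ties go to the
    smallest λ); RMSE is reported alongside.
    """

    grid: np.ndarray
    mae_by_lambda: np.ndarray
    rmse_by_lambda: np.ndarray
    lambda_star: float
    mae_star: float
    rmse_star: float


@dataclass
class ComponentDescriptor:
    """Four-descriptor summary of a connected component of size >= 2.

    Bond lengths are the O-O distances of the component's network edges;
    edge energies are the pair potential sums V_coul + V_LJ (the kinetic
    terms describe instantaneous motion, not the bond).  Spreads are
    population standard deviations (ddof = 0); zero for single-edge
    components.
    """

    component_id: int
    size: int
    sum_edge_lengths: float
    std_edge_lengths: float
    mean_edge_energy: float
    std_edge_energy: float

    def vector(self) -> np.ndarray:
        return np.array([self.sum_edge_lengths, self.std_edge_lengths,
                         self.mean_edge_energy, self.std_edge_energy])


def distribution_error(model: dict[int, float],
                       reference: dict[int, float]) -> tuple[float, float]:
    """(MAE, RMSE) between two size→fraction maps.

    The maps are aligned on the union of their sizes with missing entries
    treated as zero.

    Raises
    ------
    ValueError
        If either map is empty.
    """
    if not model or not reference:
        raise ValueError("distributions must be non-empty")
    sizes = sorted(set(model) | set(reference))
    d = np.array([model.get(s, 0.0) - reference.get(s, 0.0) for s in sizes])
    return float(np.mean(np.abs(d))), float(np.sqrt(np.mean(d * d)))


def curve_agreement(observed, predicted, x_observed=None,
                    x_predicted=None) -> AgreementMetrics:
    """R², RMSE and MAE of a predicted curve against an observed reference.

    With ``x_observed``/``x_predicted`` given and differing, the predicted
    curve is linearly interpolated onto the observed abscissa first.
    R² = 1 − SS_res/SS_tot with the observed curve as reference.

    Raises
    ------
    ValueError
        On length mismatch without abscissas, or a constant observed curve
        (SS_tot = 0 leaves R² undefined).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if x_observed is not None and x_predicted is not None:
        xo = np.asarray(x_observed, dtype=float)
        xp = np.asarray(x_predicted, dtype=float)
        pred = np.interp(xo, xp, pred)
    if obs.shape != pred.shape:
        raise ValueError("curves must be paired samples of equal length")
    resid = obs - pred
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("constant observed curve: R² undefined (SS_tot = 0)")
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot
    return AgreementMetrics(r_squared=r2,
                            rmse=float(np.sqrt(np.mean(resid ** 2))),
                            mae=float(np.mean(np.abs(resid))))


def pooled_size_fractions(frames: list[Frame], params: CriterionParameters,
                          ff: ForceFieldParameters = DEFAULT_FF) -> dict[int, float]:
    """Pooled component-size fractions of the networks of several frames."""
    counts: dict[int, int] = {}
    for frame in frames:
        dist = component_size_distribution(
            geometric_pair_table(frame, params, ff).network_at(params))
        for s, c in dist.counts.items():
            counts[s] = counts.get(s, 0) + c
    total = sum(counts.values())
    return {s: c / total for s, c in counts.items()} if total else {}


def calibrate_lambda(frames: list[Frame], reference: dict[int, float],
                     grid, params: CriterionParameters,
                     ff: ForceFieldParameters = DEFAULT_FF) -> CalibrationResult:
    """Scan a λ grid and pick the value minimising the pooled-distribution MAE.

    For each λ the networks of all frames are built (the λ-independent
    geometry and energies are computed once per frame and re-thresholded),
    component-size counts are pooled across frames and normalised to
    fractions, and the MAE/RMSE against ``reference`` are recorded.  Ties
    on MAE resolve to the smallest λ.

    Raises
    ------
    ValueError
        On an empty grid or empty frame list.
    """
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("λ grid must be non-empty")
    if not frames:
        raise ValueError("need at least one frame")
    tables = [geometric_pair_table(f, params, ff) for f in frames]
    maes = np.empty(grid.size)
    rmses = np.empty(grid.size)
    for k, lam in enumerate(grid):
        p = params.with_lambda(float(lam))
        counts: dict[int, int] = {}
        for table in tables:
            dist = component_size_distribution(table.network_at(p))
            for s, c in dist.counts.items():
                counts[s] = counts.get(s, 0) + c
        total = sum(counts.values())
        model = {s: c / total for s, c in counts.items()} if total else {1: 0.0}
        maes[k], rmses[k] = distribution_error(model, reference)
    best = int(np.argmin(maes))  # argmin takes the first (smallest λ) on ties
    return CalibrationResult(grid=grid, mae_by_lambda=maes,
                             rmse_by_lambda=rmses,
                             lambda_star=float(grid[best]),
                             mae_star=float(maes[best]),
                             rmse_star=float(rmses[best]))


def default_lambda_grid(start: float = 0.0, stop: float = 1.0,
                        step: float = 0.001) -> np.ndarray:
    """The default calibration grid: λ from 0 to 1 in steps of 0.001."""
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


def frame_coordinate_vector(frame: Frame) -> np.ndarray:
    """Flatten a frame to one row: x, y, z of H_a, O, M, H_b per molecule.

    The layout is molecule-major (4 sites × 3 coordinates each), so a frame
    of N water molecules yields 12·N columns.
    """
    if not frame.molecules:
        return np.zeros(0)
    return np.concatenate([m.positions().ravel() for m in frame.molecules])


def select_representative_frames(frames: list[Frame], n: int = 3,
                                 variance: float = 0.90) -> list[int]:
    """Indices of the n frames closest to the trajectory mean in PCA space.

    Frames are flattened to coordinate vectors, mean-centred across frames
    (no per-column scaling: all columns share units) and projected onto the
    smallest number of leading principal components explaining at least
    ``variance`` of the total variance (minimum 2).  The frames with the
    smallest Euclidean norm in the projected space — the centred mean is
    the origin — are returned; ties go to the lower index.

    If n exceeds the number of frames, all indices are returned with a
    logged warning.
    """
    if not frames:
        raise ValueError("need at least one frame")
    if n > len(frames):
        logger.warning("requested %d frames but only %d available", n,
                       len(frames))
        return list(range(len(frames)))
    x = np.stack([frame_coordinate_vector(f) for f in frames])
    xc = x - x.mean(axis=0)
    total_var = float(np.sum(xc ** 2))
    if total_var < 1e-24 or len(frames) < 3:
        # degenerate cloud (or too few frames for a meaningful subspace):
        # distances are taken in the full centred space
        dist = np.linalg.norm(xc, axis=1)
    else:
        max_comp = min(len(frames) - 1, x.shape[1])
        pca = PCA(n_components=max_comp)
        scores = pca.fit_transform(xc)
        cum = np.cumsum(pca.explained_variance_ratio_)
        k = int(np.searchsorted(cum, variance) + 1)
        k = min(max(k, 2), max_comp)
        dist = np.linalg.norm(scores[:, :k], axis=1)
    order = np.argsort(dist, kind="stable")
    return [int(i) for i in order[:n]]


def component_descriptors(net: InteractionNetwork, frame: Frame,
                          ff: ForceFieldParameters = DEFAULT_FF
                          ) -> list[ComponentDescriptor]:
    """Descriptors of every component of size >= 2 in a network.

    Components are numbered in the order returned by the component search;
    bond lengths are O-O distances of the component's edges and energies
    the per-edge potential sums.
    """
    comps = [c for c in connected_components(net) if len(c) >= 2]
    edges_by_pair = {(min(e.i, e.j), max(e.i, e.j)): e for e in net.edges}
    out: list[ComponentDescriptor] = []
    for cid, comp in enumerate(comps):
        lengths: list[float] = []
        energies: list[float] = []
        for key, e in edges_by_pair.items():
            if key[0] in comp:
                mi = frame.molecule_by_id(e.i)
                mj = frame.molecule_by_id(e.j)
                lengths.append(float(np.linalg.norm(mi.pos_O - mj.pos_O)))
                energies.append(e.potential)
        le = np.asarray(lengths)
        en = np.asarray(energies)
        out.append(ComponentDescriptor(
            component_id=cid, size=len(comp),
            sum_edge_lengths=float(le.sum()),
            std_edge_lengths=float(le.std(ddof=0)),
            mean_edge_energy=float(en.mean()),
            std_edge_energy=float(en.std(ddof=0))))
    return out


def select_representative_component(
        descriptors: list[ComponentDescriptor]) -> int:
    """Component id nearest the group mean in standardized descriptor space.

    The four descriptor fields are z-scored within the group (constant
    columns stay at zero), projected by a full-rank PCA (an isometry, so
    distances match the standardized space) and the component closest to
    the origin is returned; ties go to the lowest id.

    Raises
    ------
    ValueError
        On an empty group.
    """
    if not descriptors:
        raise ValueError("empty descriptor group")
    if len(descriptors) == 1:
        return descriptors[0].component_id
    x = np.stack([d.vector() for d in descriptors])
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0  # constant descriptors carry no information
    z = (x - mu) / sd
    if not np.any(z):
        # all candidates identical: every distance is zero, lowest id wins
        return int(min(d.component_id for d in descriptors))
    pca = PCA(n_components=min(z.shape))
    scores = pca.fit_transform(z)
    dist = np.linalg.norm(scores, axis=1)
    ids = np.array([d.component_id for d in descriptors])
    # ties within floating slack resolve to the lowest id
    near = dist <= dist.min() + 1e-9 * (1.0 + dist.min())
    return int(ids[near].min())
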