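"""Generalized Procrustes superimposition and object-symmetry symmetrization.

Form space is obtained by superimposing *without* scaling, so centroid sizes
(and hence all interlandmark distances) of the original configurations are
preserved exactly.  For bilaterally symmetric structures the symmetric
component of each configuration is extracted by averaging it with its
reflected-and-relabelled copy after rigid re-alignment, which makes every
mirror-image pair of interlandmark distances numerically identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landmark_io import LandmarkArray, SymmetryMap

__all__ = [
    "SuperimposedArray",
    "centroid_size",
    "gpa",
    "symmetrize",
    "procrustes_rotation",
]


@dataclass
class SuperimposedArray:
    """Aligned configurations plus their consensus (mean) configuration.

    ``scaled=False`` marks form space: each configuration keeps its original
    centroid size.  ``centroid_sizes`` are the pre-alignment sizes in mm.
    """

    coords: np.ndarray  # (n, q, d), each centred at the origin
    consensus: np.ndarray  # (q, d)
    centroid_sizes: np.ndarray  # (n,)
    individual_ids: list[str]
    landmark_names: list[str]
    scaled: bool = False
    symmetrized: bool = False

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def q(self) -> int:
        return self.coords.shape[1]

    @property
    def dim(self) -> int:
        return self.coords.shape[2]

    def as_landmark_array(self) -> LandmarkArray:
        return LandmarkArray(self.coords.copy(), list(self.individual_ids), list(self.landmark_names))


def centroid_size(config: np.ndarray) -> float:
    """Square root of the summed squared deviations of all landmarks from
    the configuration centroid (mm)."""
    config = np.asarray(config, dtype=float)
    centred = config - config.mean(axis=0)
    return float(np.sqrt((centred**2).sum()))


def procrustes_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation R (det = +1) minimizing ``|| source @ R - target ||``.

    Reflections are excluded by sign-flipping the smallest singular value,
    so alignment can never leak a mirror image.
    """
    u, _, vt = np.linalg.svd(source.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    flip = np.ones(source.shape[1])
    flip[-1] = d
    return (u * flip) @ vt


def gpa(
    data: LandmarkArray,
    scale: bool = False,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> SuperimposedArray:
    """Iterative generalized Procrustes alignment.

    Each configuration is centred, optionally rescaled to unit centroid size
    (``scale=True``), and rotated to the running consensus; the consensus is
    the mean of the rotated configurations and iteration stops when its
    root-mean-square change drops below ``tol``.  The final orientation is
    fixed by aligning the consensus to the first individual's centred
    configuration, making the output deterministic.
    """
    coords = data.coords.astype(float).copy()
    n = coords.shape[0]
    sizes = np.empty(n)
    for i in range(n):
        coords[i] -= coords[i].mean(axis=0)
        sizes[i] = np.sqrt((coords[i] ** 2).sum())
        if sizes[i] <= 0:
            raise ValueError(
                f"degenerate configuration (all landmarks coincident) for "
                f"individual {data.individual_ids[i]!r}"
            )
        if scale:
            coords[i] /= sizes[i]

    first = coords[0].copy()
    consensus = first.copy()
    converged = False
    for _ in range(max_iter):
        for i in range(n):
            coords[i] = coords[i] @ procrustes_rotation(coords[i], consensus)
        new_consensus = coords.mean(axis=0)
        if scale:
            norm = np.sqrt((new_consensus**2).sum())
            if norm > 0:
                new_consensus = new_consensus / norm
        # re-anchor the frame to the first configuration every iteration:
        # the mean otherwise drifts rotationally, which stalls convergence
        # of the raw consensus-change criterion without changing shape
        rot = procrustes_rotation(new_consensus, first)
        new_consensus = new_consensus @ rot
        coords = coords @ rot
        delta = np.sqrt(((new_consensus - consensus) ** 2).mean())
        consensus = new_consensus
        if delta < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(f"GPA did not converge within {max_iter} iterations")

    return SuperimposedArray(
        coords=coords,
        consensus=consensus,
        centroid_sizes=sizes,
        individual_ids=list(data.individual_ids),
        landmark_names=list(data.landmark_names),
        scaled=scale,
    )


def _reflect_relabel(config: np.ndarray, perm: np.ndarray) -> np.ndarray:
    mirrored = config.copy()
    mirrored[:, 0] *= -1.0  # any fixed axis works up to rotation
    return mirrored[perm]


def symmetrize(data: SuperimposedArray, smap: SymmetryMap) -> SuperimposedArray:
    """Extract the symmetric component of each aligned configuration.

    For every individual the mirrored copy (one axis negated, left/right
    labels swapped) is rigidly aligned back to the original and the two are
    averaged; the averaging is iterated to its fixed point so the result is
    exactly invariant under reflect-and-relabel (up to rounding).  The
    symmetrized set then re-enters a no-scaling GPA.
    """
    smap.validate_for(data.q)
    perm = smap.sigma()
    sym = data.coords.astype(float).copy()
    for i in range(sym.shape[0]):
        x = sym[i]
        for _ in range(60):
            mirrored = _reflect_relabel(x, perm)
            mirrored = mirrored @ procrustes_rotation(mirrored, x)
            new = 0.5 * (x + mirrored)
            if np.abs(new - x).max() < 1e-13:
                x = new
                break
            x = new
        sym[i] = x

    arr = LandmarkArray(sym, list(data.individual_ids), list(data.landmark_names))
    out = gpa(arr, scale=data.scaled)
    out.symmetrized = True
    return out


def asymmetry(data: SuperimposedArray | LandmarkArray, smap: SymmetryMap) -> float:
    """Largest coordinate deviation (mm) of any configuration from its
    reflected-relabelled-realigned copy; 0 for perfectly symmetric data."""
    coords = data.coords
    perm = smap.sigma()
    worst = 0.0
    for i in range(coords.shape[0]):
        x = coords[i] - coords[i].mean(axis=0)
        mirrored = _reflect_relabel(x, perm)
        mirrored = mirrored @ procrustes_rotation(mirrored, x)
        worst = max(worst, float(np.abs(mirrored - x).max()))
    return worst
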