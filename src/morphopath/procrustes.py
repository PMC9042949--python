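"""Generalized Procrustes analysis with optional sliding semi-landmarks.

Superimposition removes translation, scale and rotation (never reflection:
faces have a consistent orientation) and iterates alignment against a running
consensus. With ``slide=True`` each outer iteration additionally slides every
semi-landmark along its local curve tangent towards the position minimising
that specimen's squared Procrustes distance to the consensus, then
re-superimposes.

Conventions
-----------
* Every aligned configuration is centred at the origin and scaled to unit
  centroid size (classical full Procrustes). An optional post-hoc orthogonal
  projection to the tangent space is available but off by default; at facial
  shape-variation magnitudes it changes downstream scores negligibly.
* The consensus is the arithmetic mean of the aligned configurations,
  re-normalised to unit centroid size — which is exactly the unit-size shape
  minimising the summed squared distances, so the outer loop is a coordinate
  descent with a monotone objective.
* Sliding displacement is solved in closed form as the 1-D projection of the
  residual onto the tangent (chord between curve neighbours; one-sided at
  curve endpoints), capped at half the distance to the nearer neighbour to
  prevent curve inversion. A bending-energy criterion is not implemented;
  the Procrustes-distance criterion is the package default and only option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import DegenerateShapeError
from .landmarks import LandmarkConfiguration, LandmarkScheme

__all__ = [
    "AlignedSample",
    "centroid_size",
    "opa_align",
    "procrustes_distance",
    "gpa",
]


def centroid_size(points: np.ndarray) -> float:
    """Root summed squared distance of landmarks from their centroid."""
    centred = points - points.mean(axis=0)
    return float(np.sqrt(np.sum(centred ** 2)))


def _centre_and_scale(points: np.ndarray) -> tuple[np.ndarray, float]:
    centred = points - points.mean(axis=0)
    size = float(np.sqrt(np.sum(centred ** 2)))
    if size <= 0 or not np.isfinite(size):
        raise DegenerateShapeError("configuration has zero centroid size")
    return centred / size, size


def _optimal_rotation(target: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Rotation R (no reflection) minimising ||target @ R - reference||_F."""
    m = target.T @ reference
    u, _, vt = np.linalg.svd(m)
    d = np.sign(np.linalg.det(u @ vt))
    # force det(R) = +1: flip the smallest singular direction if needed
    r = u @ np.diag([1.0, d]) @ vt
    return r


def opa_align(reference: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, float]:
    """Ordinary Procrustes alignment of ``target`` onto ``reference``.

    Both configurations are centred and scaled to unit centroid size; the
    target is then rotated (rotation only) to minimise the summed squared
    distance to the reference. Returns the rotated unit-size target and the
    minimised root-summed-squared distance.
    """
    reference = np.asarray(reference, dtype=float)
    target = np.asarray(target, dtype=float)
    if reference.shape != target.shape:
        raise ValueError(
            f"landmark count mismatch: {reference.shape} vs {target.shape}"
        )
    ref, _ = _centre_and_scale(reference)
    tgt, _ = _centre_and_scale(target)
    rot = _optimal_rotation(tgt, ref)
    aligned = tgt @ rot
    return aligned, float(np.linalg.norm(aligned - ref))


def procrustes_distance(shape_a: np.ndarray, shape_b: np.ndarray) -> float:
    """Root summed squared coordinate difference between two aligned shapes."""
    shape_a = np.asarray(shape_a, dtype=float)
    shape_b = np.asarray(shape_b, dtype=float)
    if shape_a.shape != shape_b.shape:
        raise ValueError(
            f"landmark count mismatch: {shape_a.shape} vs {shape_b.shape}"
        )
    return float(np.linalg.norm(shape_a - shape_b))


@dataclass
class AlignedSample:
    """Procrustes-superimposed sample: shapes, consensus and centroid sizes."""

    aligned: np.ndarray        # (n, k, 2), unit centroid size each
    consensus: np.ndarray      # (k, 2), unit centroid size
    centroid_sizes: np.ndarray  # (n,) original digitising-unit sizes
    iterations: int
    converged: bool
    specimen_ids: list[str]
    scheme: LandmarkScheme | None = None
    objective_trace: list[float] | None = None  # total SS to consensus per iter

    @property
    def n_specimens(self) -> int:
        return self.aligned.shape[0]

    @property
    def flat(self) -> np.ndarray:
        """Aligned coordinates flattened to (n, 2k) row vectors."""
        return self.aligned.reshape(self.n_specimens, -1)

    def distances_to_consensus(self) -> np.ndarray:
        diff = self.aligned - self.consensus[None]
        return np.sqrt(np.sum(diff ** 2, axis=(1, 2)))

    def save(self, directory: str | Path) -> None:
        """Serialise to a plain-text bundle (consensus, coordinates, sizes)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savetxt(directory / "consensus.txt", self.consensus)
        np.savetxt(directory / "aligned.txt", self.flat)
        np.savetxt(directory / "centroid_sizes.txt", self.centroid_sizes)
        (directory / "specimen_ids.txt").write_text(
            "\n".join(self.specimen_ids) + "\n"
        )
        (directory / "meta.txt").write_text(
            f"iterations={self.iterations}\nconverged={self.converged}\n"
        )


def _slide_one(points: np.ndarray, consensus: np.ndarray,
               scheme: LandmarkScheme) -> np.ndarray:
    """Slide each semi-landmark of one aligned configuration along its tangent.

    Tangent at semi-landmark j is the normalised chord between its curve
    neighbours (one-sided at endpoints). The optimal displacement along the
    tangent for minimising ||x_j + t*lam - c_j||^2 is lam = (c_j - x_j)@t,
    capped at half the distance to the nearer neighbour.
    """
    slid = points.copy()
    for j in scheme.semi_indices:
        prev, nxt = scheme.curve_neighbours(j)
        if prev is None and nxt is None:
            continue
        a = points[prev] if prev is not None else points[j]
        b = points[nxt] if nxt is not None else points[j]
        chord = b - a
        norm = np.linalg.norm(chord)
        if norm <= 0:
            continue
        tangent = chord / norm
        lam = float((consensus[j] - points[j]) @ tangent)
        dists = [np.linalg.norm(points[j] - points[i])
                 for i in (prev, nxt) if i is not None]
        cap = 0.5 * min(dists)
        lam = float(np.clip(lam, -cap, cap))
        slid[j] = points[j] + lam * tangent
    return slid


def gpa(
    configs: list[LandmarkConfiguration] | np.ndarray,
    scheme: LandmarkScheme | None = None,
    slide: bool = False,
    tol: float = 1e-6,
    max_iter: int = 20,
    slide_iters: int = 5,
    specimen_ids: list[str] | None = None,
) -> AlignedSample:
    """Generalized Procrustes superimposition of >= 2 configurations.

    Iterates (align all to consensus, update consensus) until the consensus
    root-mean-square change falls below ``tol`` or ``max_iter`` outer
    iterations. With ``slide=True`` (``scheme`` required) the first
    ``slide_iters`` outer iterations additionally slide each semi-landmark
    against the current consensus; sliding is then frozen and the
    superimposition run to convergence. The cut-off exists because the
    tangential position of a semi-landmark is a nuisance degree of freedom:
    unlimited alternation lets the whole sample creep along its curves
    without meaningful shape change. Non-convergence returns
    ``converged=False`` with a warning rather than raising.
    """
    if isinstance(configs, np.ndarray):
        arrays = [configs[i] for i in range(configs.shape[0])]
        ids = specimen_ids or [str(i) for i in range(len(arrays))]
    else:
        arrays = [c.points for c in configs]
        ids = specimen_ids or [c.specimen_id for c in configs]
    if len(arrays) < 2:
        raise ValueError("GPA needs at least 2 configurations")
    counts = {a.shape[0] for a in arrays}
    if len(counts) > 1:
        raise ValueError(f"inconsistent landmark counts: {sorted(counts)}")
    if slide and scheme is None:
        raise ValueError("slide=True requires a landmark scheme")
    if scheme is not None and scheme.n_landmarks != arrays[0].shape[0]:
        raise ValueError("scheme landmark count does not match configurations")

    sizes = np.array([centroid_size(a) for a in arrays])
    shapes = np.stack([_centre_and_scale(a)[0] for a in arrays])
    n = shapes.shape[0]

    # initial consensus: first shape (unit size already)
    consensus = shapes[0].copy()
    converged = False
    iterations = 0
    trace: list[float] = []
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            rot = _optimal_rotation(shapes[i], consensus)
            shapes[i] = shapes[i] @ rot
        if slide and iterations <= slide_iters:
            for i in range(n):
                slid = _slide_one(shapes[i], consensus, scheme)
                slid, _ = _centre_and_scale(slid)
                rot = _optimal_rotation(slid, consensus)
                shapes[i] = slid @ rot
        mean = shapes.mean(axis=0)
        mean = mean - mean.mean(axis=0)
        new_consensus = mean / np.sqrt(np.sum(mean ** 2))
        change = float(np.sqrt(np.mean((new_consensus - consensus) ** 2)))
        consensus = new_consensus
        trace.append(float(np.sum((shapes - consensus[None]) ** 2)))
        if change < tol and iterations > 1 and not (slide and
                                                    iterations <= slide_iters):
            converged = True
            break
    if not converged:
        warnings.warn(
            f"GPA did not converge in {max_iter} iterations", stacklevel=2
        )
    return AlignedSample(
        aligned=shapes,
        consensus=consensus,
        centroid_sizes=sizes,
        iterations=iterations,
        converged=converged,
        specimen_ids=list(ids),
        scheme=scheme,
        objective_trace=trace,
    )
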