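"""Fluorescent spot energetics and subpixel localization.

The image around detected foci is modelled as a constant background plus 2D
circular Gaussians of fixed width (sigma = 3 px) centred on the candidate
pixels; solving the linear least-squares problem for the background and the
per-spot amplitudes yields the spot "energy" coefficients.  Candidate
centres are then refined to subpixel resolution with a median-background
weighted centroid over a circular neighbourhood.
"""

from __future__ import annotations

import numpy as np

__all__ = ["spot_energy", "subpixel_refine", "gaussian_spot", "UndefinedSpotError"]

DEFAULT_SIGMA = 3.0
#: Neighbourhood radius for the centroid refinement.  Roughly 2.5 sigma of
#: the spot model; measured to minimise the localization error on synthetic
#: spots (smaller windows lose signal to the median estimate, larger ones
#: accumulate background noise on long lever arms).
DEFAULT_RADIUS = 8


class UndefinedSpotError(ValueError):
    """No pixel in the neighbourhood rises above the local median background."""


def gaussian_spot(shape, center, sigma: float = DEFAULT_SIGMA) -> np.ndarray:
    """Unit-amplitude circular Gaussian exp(-((x-x0)^2+(y-y0)^2)/(2 sigma^2)).

    ``center`` is (row, col) in pixel coordinates (may be subpixel).
    """
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return np.exp(-((rr - center[0]) ** 2 + (cc - center[1]) ** 2)
                  / (2.0 * sigma**2))


def spot_energy(image: np.ndarray, centers, sigma: float = DEFAULT_SIGMA):
    """Least-squares background and per-spot Gaussian amplitudes.

    Solves ``image ~ b + sum_k a_k G(center_k, sigma)`` in the least-squares
    sense.  Returns ``(background, amplitudes)``; the amplitudes are the spot
    energy values.  Duplicate centres make the design singular and raise.
    """
    image = np.asarray(image, dtype=float)
    if not np.isfinite(image).all():
        raise ValueError("image contains non-finite intensities")
    centers = [tuple(map(float, c)) for c in np.atleast_2d(centers)]
    if len(centers) == 0:
        raise ValueError("need at least one candidate centre")
    if len(set(centers)) != len(centers):
        raise ValueError("duplicate candidate centres (singular design)")
    for (r, c) in centers:
        if not (0 <= r < image.shape[0] and 0 <= c < image.shape[1]):
            raise ValueError(f"candidate centre {(r, c)} outside image")
    cols = [np.ones(image.size)]
    for c in centers:
        cols.append(gaussian_spot(image.shape, c, sigma).ravel())
    A = np.column_stack(cols)
    coef, _, rank, _ = np.linalg.lstsq(A, image.ravel(), rcond=None)
    if rank < A.shape[1]:
        raise ValueError("singular design (overlapping/duplicate centres)")
    return float(coef[0]), coef[1:]


def subpixel_refine(image: np.ndarray, center, radius: int = DEFAULT_RADIUS):
    """Median-background weighted centroid in a circular neighbourhood.

    Weights are the intensities minus the neighbourhood median; only pixels
    strictly above the median contribute.  Returns (row, col) subpixel
    coordinates.  Raises :class:`UndefinedSpotError` if no pixel exceeds the
    median (e.g. a flat image).
    """
    image = np.asarray(image, dtype=float)
    r0, c0 = int(round(center[0])), int(round(center[1]))
    if not (radius <= r0 < image.shape[0] - radius
            and radius <= c0 < image.shape[1] - radius):
        raise ValueError("neighbourhood extends outside the image")
    rr, cc = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    disk = rr**2 + cc**2 <= radius**2
    rows = r0 + rr[disk]
    cols = c0 + cc[disk]
    vals = image[rows, cols]
    med = np.median(vals)
    above = vals > med
    if not above.any():
        raise UndefinedSpotError("no pixel above the local median background")
    w = vals[above] - med
    return (float(np.sum(w * rows[above]) / w.sum()),
            float(np.sum(w * cols[above]) / w.sum()))
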