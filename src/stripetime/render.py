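"""Forward renderer: synthetic embryos to multi-channel z-stacks.

Channel 0 carries nuclear protein over a uniform cytoplasmic background;
channel 1 carries Gaussian nuclear-marker blobs plus diffraction-limited
transcription spots whose signal spreads over adjacent z-planes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import EmbryoDataset


@dataclass
class RenderParams:
    shape: tuple[int, int] = (128, 128)  # (ny, nx)
    n_z: int = 5
    nuclear_sigma: float = 4.0  # px
    spot_sigma: float = 1.2  # px, in-plane point spread
    spot_sigma_z: float = 0.8  # planes
    marker_level: float = 100.0
    protein_scale: float = 100.0
    background_protein: float = 10.0
    background_marker: float = 5.0
    spot_scale: float = 200.0
    noise_sd: float = 0.0


def _blob(shape, x, y, sigma):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2.0 * sigma**2))


def render_frame(
    positions: np.ndarray,
    protein: np.ndarray,
    spot_intensity: np.ndarray,
    params: RenderParams | None = None,
    spot_z: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one timepoint as a (Z, C, Y, X) array.

    positions: (n, 2) array of (x, y); protein and spot_intensity: per
    nucleus (a.u., spot 0 = silent); spot_z: sub-plane z position of each
    spot (defaults to the central plane).
    """
    params = params or RenderParams()
    ny, nx = params.shape
    n_z = params.n_z
    out = np.zeros((n_z, 2, ny, nx))
    out[:, 0] += params.background_protein
    out[:, 1] += params.background_marker
    if spot_z is None:
        spot_z = np.full(len(positions), (n_z - 1) / 2.0)
    for k in range(len(positions)):
        x, y = positions[k]
        blob = _blob((ny, nx), x, y, params.nuclear_sigma)
        for z in range(n_z):
            out[z, 0] += params.protein_scale * protein[k] * blob
            out[z, 1] += params.marker_level * blob
        if spot_intensity[k] > 0:
            spot = _blob((ny, nx), x, y, params.spot_sigma)
            for z in range(n_z):
                zw = np.exp(-((z - spot_z[k]) ** 2) / (2.0 * params.spot_sigma_z**2))
                out[z, 1] += params.spot_scale * spot_intensity[k] * zw * spot
    if rng is not None and params.noise_sd > 0:
        out = out + rng.normal(0.0, params.noise_sd, out.shape)
    return out


def render_image_stack(
    embryo: EmbryoDataset,
    frames: list[int] | None = None,
    params: RenderParams | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render selected frames of an embryo as a (T, Z, C, Y, X) stack.

    Positions are scaled to fit the target field of view.
    """
    params = params or RenderParams()
    frames = frames if frames is not None else list(range(len(embryo.t)))
    ids = sorted(embryo.traces)
    ny, nx = params.shape
    xs = np.array([embryo.traces[i].x for i in ids])
    ys = np.array([embryo.traces[i].y for i in ids])
    margin = 4 * params.nuclear_sigma
    x0, x1 = np.nanmin(xs), np.nanmax(xs)
    y0, y1 = np.nanmin(ys), np.nanmax(ys)
    sx = (nx - 2 * margin) / max(x1 - x0, 1e-9)
    sy = (ny - 2 * margin) / max(y1 - y0, 1e-9)
    stack = np.zeros((len(frames), params.n_z, 2, ny, nx))
    for fi, f in enumerate(frames):
        pos = np.column_stack(
            [margin + (xs[:, f] - x0) * sx, margin + (ys[:, f] - y0) * sy]
        )
        prot = np.array([embryo.traces[i].protein[f] for i in ids])
        spot = np.array([embryo.traces[i].spot[f] for i in ids])
        stack[fi] = render_frame(pos, prot, spot, params, rng=rng)
    return stack
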