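"""Zero-mean normalized cross-correlation matching with sub-pixel refinement.

Thin wrapper around :func:`skimage.feature.match_template` shared by the
template gaze tracker and the strip registration stage.  The returned
offset is the translation ``(dx, dy)`` (columns, rows; positive
right/down) that maps the template's nominal position in the search
image to its best-matching position.
"""

from __future__ import annotations

import numpy as np
from skimage.feature import match_template

__all__ = ["ncc_map", "match_offset", "parabolic_subpixel"]


def ncc_map(image: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Zero-mean NCC of ``template`` at every valid position in ``image``.

    Output shape is ``image.shape - template.shape + 1``; values in
    [-1, 1].  Positions where either window is constant yield 0.
    """
    image = np.asarray(image, dtype=np.float64)
    template = np.asarray(template, dtype=np.float64)
    if template.shape[0] > image.shape[0] or template.shape[1] > image.shape[1]:
        raise ValueError("template larger than search image")
    if template.std() == 0:
        return np.zeros(
            (image.shape[0] - template.shape[0] + 1,
             image.shape[1] - template.shape[1] + 1)
        )
    out = match_template(image, template, pad_input=False)
    return np.nan_to_num(np.clip(out, -1.0, 1.0))


def parabolic_subpixel(values: np.ndarray, peak: int) -> float:
    """Sub-pixel peak position from a 3-point parabolic fit along one axis."""
    if peak <= 0 or peak >= len(values) - 1:
        return float(peak)
    y0, y1, y2 = values[peak - 1], values[peak], values[peak + 1]
    denom = y0 - 2 * y1 + y2
    if abs(denom) < 1e-12:
        return float(peak)
    delta = 0.5 * (y0 - y2) / denom
    return float(peak + np.clip(delta, -0.5, 0.5))


def match_offset(
    image: np.ndarray,
    template: np.ndarray,
    template_pos: tuple[int, int],
    subpixel: bool = True,
) -> tuple[float, float, float]:
    """Best-match displacement of ``template`` within ``image``.

    ``template_pos`` is the (row, col) of the template's top-left corner
    in the frame it was cut from.  Returns ``(dx, dy, ncc)`` where the
    template content is found displaced by (dx, dy) in ``image``
    relative to that nominal position.
    """
    corr = ncc_map(image, template)
    flat = int(np.argmax(corr))
    py, px = np.unravel_index(flat, corr.shape)
    ncc = float(corr[py, px])
    if subpixel:
        sy = parabolic_subpixel(corr[:, px], py)
        sx = parabolic_subpixel(corr[py, :], px)
    else:
        sy, sx = float(py), float(px)
    dy = sy - template_pos[0]
    dx = sx - template_pos[1]
    return dx, dy, ncc
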