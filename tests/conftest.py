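import numpy as np
import pytest

from odfkit import RenderConfig, SegmentationConfig

FILM_RGB = (214, 46, 122)
BG_RGB = (226, 209, 199)


@pytest.fixture
def small_render() -> RenderConfig:
    """Quarter-resolution camera for fast rendering in unit tests."""
    return RenderConfig(
        width_px=160,
        height_px=120,
        mm_per_px=0.25,
        fps=10.0,
        corner_radius_px=4.0,
        noise_sd=3.0,
    )


@pytest.fixture
def seg_config() -> SegmentationConfig:
    return SegmentationConfig()


def flat_frame(h: int, w: int, rgb=BG_RGB) -> np.ndarray:
    """Uniform background frame."""
    frame = np.empty((h, w, 3), dtype=np.uint8)
    frame[:] = rgb
    return frame


def frame_with_rect(h: int, w: int, top: int, left: int, rh: int, rw: int) -> np.ndarray:
    """Background frame with one film-coloured rectangle."""
    frame = flat_frame(h, w)
    frame[top : top + rh, left : left + rw] = FILM_RGB
    return frame


def bfs_label(mask: np.ndarray) -> int:
    """Exhaustive 8-connected component count by breadth-first flood fill.

    Deliberately naive: an independent oracle for the pipeline's labelling.
    """
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    h, w = mask.shape
    n = 0
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                n += 1
                stack = [(r, c)]
                seen[r, c] = True
                while stack:
                    y, x = stack.pop()
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            yy, xx = y + dy, x + dx
                            if 0 <= yy < h and 0 <= xx < w and mask[yy, xx] and not seen[yy, xx]:
                                seen[yy, xx] = True
                                stack.append((yy, xx))
    return n


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    a, b = np.asarray(a, bool), np.asarray(b, bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return np.logical_and(a, b).sum() / union
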