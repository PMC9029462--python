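"""Synthetic plan-view video of a dyed film disintegrating on a tongue.

Renders a :class:`~odfkit.scenarios.FilmScenario` into an RGB frame sequence
with per-frame ground-truth masks. The film is drawn as a rounded-corner
rectangle of saturated pink (the Sulforhodamine B dye) on a pale
silicone-tone background; the scripted event schedule is realised
geometrically (a tear opens a gap, a detached fragment translates away and
off the tongue, a coalesce closes a prior tear), and method-specific
artifacts are injected: the oral cavity model contributes a brief brightness
haze on every 2 s compression, the tribometer a moving specular band from
the reciprocating acrylic palate.

Frames are rendered lazily and deterministically: frame ``i`` depends only
on (scenario, seed, i), so a three-minute video at 30 fps never has to be
materialised in memory.
"""

from __future__ import annotations

import math
from typing import Iterator, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .scenarios import FilmScenario

__all__ = ["RenderConfig", "FrameSequence", "render_video"]


class RenderConfig(BaseModel):
    """Camera and appearance settings for the synthetic recordings."""

    model_config = ConfigDict(frozen=True)

    width_px: int = Field(640, gt=0)
    height_px: int = Field(480, gt=0)
    mm_per_px: float = Field(0.1, gt=0)
    fps: float = Field(30.0, gt=0)
    corner_radius_px: float = Field(12.0, ge=0)
    film_rgb: tuple[int, int, int] = (214, 46, 122)
    bg_rgb: tuple[int, int, int] = (226, 209, 199)
    noise_sd: float = Field(4.0, ge=0, description="per-pixel Gaussian noise, 8-bit units")
    artifacts: bool = True
    compression_period_s: float = Field(2.0, gt=0)
    compression_len_s: float = Field(0.15, gt=0)
    compression_haze: float = Field(0.15, ge=0, le=1)
    btm_band_halfwidth_px: int = Field(20, gt=0)
    btm_band_alpha: float = Field(0.30, ge=0, le=1)
    btm_stroke_mm: float = Field(7.5, gt=0)
    btm_freq_hz: float = Field(1.0, gt=0)


def _rounded_rect(dx: np.ndarray, dy: np.ndarray, hw: float, hh: float, r: float) -> np.ndarray:
    ax, ay = np.abs(dx), np.abs(dy)
    inside = (ax <= hw) & (ay <= hh)
    if r > 0:
        cx, cy = ax - (hw - r), ay - (hh - r)
        corner = (cx > 0) & (cy > 0) & (cx * cx + cy * cy > r * r)
        inside &= ~corner
    return inside


class FrameSequence:
    """Lazily rendered RGB frames plus aligned ground-truth masks.

    Sequence-like: ``len(seq)``, ``seq[i]`` (RGB uint8 frame), ``seq.mask(i)``
    (boolean ground-truth raster), ``seq.times`` (frame times, s).
    """

    def __init__(self, scenario: FilmScenario, seed: int, config: Optional[RenderConfig] = None):
        self.scenario = scenario
        self.seed = int(seed)
        self.config = config or RenderConfig()
        c = self.config
        self.n_frames = int(round(scenario.duration_s * c.fps))
        self.fps = c.fps
        self.mm_per_px = c.mm_per_px

        self._film_w_px = scenario.film.width_mm / c.mm_per_px
        self._film_h_px = scenario.film.height_mm / c.mm_per_px
        if self._film_w_px > c.width_px or self._film_h_px > c.height_px:
            raise ValueError(
                "film does not fit in the frame: "
                f"{self._film_w_px:.0f}x{self._film_h_px:.0f} px film vs "
                f"{c.width_px}x{c.height_px} px frame"
            )
        cx, cy = c.width_px / 2.0, c.height_px / 2.0
        ys, xs = np.mgrid[0 : c.height_px, 0 : c.width_px]
        self._dx = (xs + 0.5 - cx).astype(np.float32)
        self._dy = (ys + 0.5 - cy).astype(np.float32)

        # resolve the event schedule once: tears keyed by onset with their
        # closing (coalesce) time, plus shrink/swell/detach lists
        self._tears: list[dict] = []
        self._detaches: list[dict] = []
        self._shrinks: list[tuple[float, float]] = []
        self._swells: list[tuple[float, float, float]] = []
        closes = {
            e.params["target_onset_s"]: e.onset_s
            for e in scenario.events
            if e.kind == "coalesce"
        }
        for e in scenario.events:
            if e.kind == "tear":
                self._tears.append(
                    {
                        "onset": e.onset_s,
                        "close": closes.get(e.onset_s, math.inf),
                        "region": e.params.get("region", "vertical"),
                        "x_frac": e.params.get("x_frac", 0.5),
                        "area_frac": e.params.get("area_frac", 0.05),
                        "gap": float(e.params.get("gap_px", 4)),
                        "split_s": e.params.get("split_s"),  # None => persistent split
                    }
                )
            elif e.kind == "detach":
                self._detaches.append(
                    {
                        "onset": e.onset_s,
                        "area_frac": e.params.get("area_frac", 0.1),
                        "gap": float(e.params.get("gap_px", 4)),
                        "speed": float(e.params.get("speed_px_s", 30.0)),
                        "leave": float(e.params.get("leave_px", 160.0)),
                    }
                )
            elif e.kind == "shrink":
                self._shrinks.append((e.onset_s, float(e.params["rate_frac_per_s"])))
            elif e.kind == "swell":
                self._swells.append(
                    (e.onset_s, float(e.params["factor"]), float(e.params.get("ramp_s", 60.0)))
                )

    # -- sequence protocol ---------------------------------------------------

    def __len__(self) -> int:
        return self.n_frames

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps

    def __getitem__(self, i: int) -> np.ndarray:
        return self.frame(i)

    def __iter__(self) -> Iterator[np.ndarray]:
        return (self.frame(i) for i in range(self.n_frames))

    # -- ground truth ---------------------------------------------------------

    def _scale(self, t: float) -> float:
        s = 1.0
        for onset, factor, ramp in self._swells:
            if t >= onset:
                s *= 1.0 + (factor - 1.0) * min(1.0, (t - onset) / ramp)
        area = 1.0
        for onset, rate in self._shrinks:
            if t > onset:
                area *= max(0.05, 1.0 - rate * (t - onset))
        return s * math.sqrt(area)

    def mask_at(self, t: float) -> np.ndarray:
        """Ground-truth film mask at time ``t`` seconds."""
        c = self.config
        scale = self._scale(t)
        hw = 0.5 * self._film_w_px * scale
        hh = 0.5 * self._film_h_px * scale
        r = c.corner_radius_px * scale
        dx, dy = self._dx, self._dy
        base = _rounded_rect(dx, dy, hw, hh, r)
        mask = base.copy()

        for tear in self._tears:
            if not (tear["onset"] <= t < tear["close"]):
                continue
            gap = tear["gap"]
            if tear["region"] == "vertical":
                x_off = (tear["x_frac"] - 0.5) * 2.0 * hw
                band = base & (np.abs(dx - x_off) < gap / 2.0)
                if tear["split_s"] is not None and t >= tear["onset"] + tear["split_s"]:
                    band &= ~(np.abs(dy) < 6.0)  # connecting bridge re-forms
                mask &= ~band
            else:  # corner: bottom-right fragment separated by an L-shaped gap
                f = tear["area_frac"]
                cw = 2.0 * hw * math.sqrt(f)
                ch = 2.0 * hh * math.sqrt(f)
                bx, by = hw - cw, hh - ch
                in_corner = (dx >= bx) & (dy >= by)
                band = base & (dx >= bx - gap) & (dy >= by - gap) & ~in_corner
                if tear["split_s"] is not None and t >= tear["onset"] + tear["split_s"]:
                    band &= ~(dy > hh - 8.0)  # bridge along the bottom edge
                mask &= ~band

        for det in self._detaches:
            if t < det["onset"]:
                continue
            x_cut = hw * (1.0 - 2.0 * det["area_frac"])
            frag_region = base & (dx > x_cut)
            mask &= ~frag_region
            shift = det["gap"] + det["speed"] * (t - det["onset"])
            if shift <= det["leave"]:
                sdx = dx - np.float32(shift)
                frag = _rounded_rect(sdx, dy, hw, hh, r) & (sdx > x_cut)
                mask |= frag
        return mask

    def mask(self, i: int) -> np.ndarray:
        if not 0 <= i < self.n_frames:
            raise IndexError(i)
        return self.mask_at(i / self.fps)

    def ground_truth_masks(self) -> Iterator[np.ndarray]:
        return (self.mask(i) for i in range(self.n_frames))

    # -- appearance -----------------------------------------------------------

    def frame(self, i: int) -> np.ndarray:
        if not 0 <= i < self.n_frames:
            raise IndexError(i)
        c = self.config
        t = i / self.fps
        mask = self.mask(i)
        img = np.empty((c.height_px, c.width_px, 3), dtype=np.float32)
        img[:] = np.asarray(c.bg_rgb, dtype=np.float32)
        img[mask] = np.asarray(c.film_rgb, dtype=np.float32)

        if c.artifacts and self.scenario.method == "ocm":
            if (t % c.compression_period_s) < c.compression_len_s:
                img = img * (1.0 - c.compression_haze) + 255.0 * c.compression_haze
        if c.artifacts and self.scenario.method == "btm":
            phase = (t * c.btm_freq_hz) % 1.0
            tri = 1.0 - abs(2.0 * phase - 1.0)
            stroke_px = c.btm_stroke_mm / c.mm_per_px
            band_x = c.width_px / 2.0 + stroke_px * (tri - 0.5)
            band = np.abs((self._dx + c.width_px / 2.0) - band_x) < c.btm_band_halfwidth_px
            img[band] = img[band] * (1.0 - c.btm_band_alpha) + 255.0 * c.btm_band_alpha

        if c.noise_sd > 0:
            # luminance (sensor) noise, shared across channels
            rng = np.random.default_rng([self.seed, i])
            img += (
                c.noise_sd * rng.standard_normal(img.shape[:2], dtype=np.float32)
            )[..., None]
        np.clip(img, 0.0, 255.0, out=img)
        return img.astype(np.uint8)


def render_video(
    scenario: FilmScenario, seed: int, config: Optional[RenderConfig] = None
) -> FrameSequence:
    """Render a scenario into a lazy frame sequence with ground-truth masks."""
    return FrameSequence(scenario, seed, config)
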