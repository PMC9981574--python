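"""Frame ingestion and rolling-mean background modelling.

The flow-cell camera records a static scene in which only the animals
(and the occasional drifting particle) move, so the per-pixel mean over
a trailing window is an adequate background estimate. The window default
is 20 s of video (``fps * 20`` frames): detection is suppressed until
the buffer has filled once, after which the model either keeps rolling
(default) or can be frozen.

Subtraction is the per-pixel *absolute* difference, so both darker and
lighter objects produce positive responses.
"""

from __future__ import annotations

import os
from collections import deque
from pathlib import Path

import numpy as np

_IMAGE_EXTS = {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"}


class NotWarmedUpError(RuntimeError):
    """Raised when subtraction is requested before the background buffer is full."""


def to_gray(frame: np.ndarray) -> np.ndarray:
    """Convert an image to grayscale by luminance; grayscale passes through."""
    if frame.ndim == 2:
        return frame
    if frame.ndim == 3 and frame.shape[2] in (3, 4):
        rgb = frame[..., :3].astype(np.float64)
        return rgb @ np.array([0.2989, 0.5870, 0.1140])
    raise ValueError(f"unsupported frame shape {frame.shape}")


class BackgroundModel:
    """Per-pixel arithmetic mean over the last ``window_frames`` frames.

    Parameters
    ----------
    window_frames:
        Buffer capacity; the paper-default configuration is fps * 20.
    freeze_after_warmup:
        If true, the mean stops updating once the buffer has filled.
    """

    def __init__(self, window_frames: int, freeze_after_warmup: bool = False):
        if window_frames < 1:
            raise ValueError("window_frames must be >= 1")
        self.window_frames = int(window_frames)
        self.freeze_after_warmup = bool(freeze_after_warmup)
        self._buffer: deque[np.ndarray] = deque()
        self._sum: np.ndarray | None = None
        self._shape: tuple[int, int] | None = None

    @property
    def warmed_up(self) -> bool:
        return len(self._buffer) >= self.window_frames

    @property
    def n_buffered(self) -> int:
        return len(self._buffer)

    @property
    def mean_image(self) -> np.ndarray:
        if self._sum is None or not self._buffer:
            raise NotWarmedUpError("no frames buffered yet")
        return self._sum / len(self._buffer)

    def update(self, frame: np.ndarray) -> "BackgroundModel":
        """Fold one frame into the rolling mean; returns self for chaining."""
        frame = np.asarray(frame, dtype=np.float64)
        if frame.ndim != 2:
            raise ValueError("background model consumes 2-D grayscale frames")
        if self._shape is None:
            self._shape = frame.shape
            self._sum = np.zeros(self._shape, dtype=np.float64)
        elif frame.shape != self._shape:
            raise ValueError(f"frame shape {frame.shape} does not match model shape {self._shape}")
        if self.freeze_after_warmup and self.warmed_up:
            return self
        self._buffer.append(frame)
        self._sum += frame
        if len(self._buffer) > self.window_frames:
            self._sum -= self._buffer.popleft()
        return self


def subtract(frame: np.ndarray, background: BackgroundModel | np.ndarray) -> np.ndarray:
    """Absolute per-pixel difference between a frame and the background mean.

    Raises :class:`NotWarmedUpError` when given an unfilled model: frames
    inside the warm-up window produce no detections downstream.
    """
    if isinstance(background, BackgroundModel):
        if not background.warmed_up:
            raise NotWarmedUpError(
                f"background has {background.n_buffered}/{background.window_frames} frames"
            )
        mean = background.mean_image
    else:
        mean = np.asarray(background, dtype=np.float64)
    frame = np.asarray(frame, dtype=np.float64)
    if frame.shape != mean.shape:
        raise ValueError("frame/background shape mismatch")
    return np.abs(frame - mean)


def load_frames(
    source: str | os.PathLike,
    roi: tuple[int, int, int, int] | None = None,
) -> list[np.ndarray]:
    """Load grayscale frames from a directory of images or a video file.

    Directory entries are taken in lexicographic order. ``roi`` is an
    optional (x, y, w, h) crop applied to every frame.
    """
    import imageio.v3 as iio

    path = Path(source)
    frames: list[np.ndarray] = []
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _IMAGE_EXTS)
        if not files:
            raise FileNotFoundError(f"no image frames found in {path}")
        for f in files:
            frames.append(to_gray(iio.imread(f)))
    elif path.is_file():
        for frame in iio.imiter(path):
            frames.append(to_gray(np.asarray(frame)))
    else:
        raise FileNotFoundError(str(path))
    if roi is not None:
        x, y, w, h = roi
        frames = [f[y : y + h, x : x + w] for f in frames]
    return frames


def write_frames(frames, out_dir: str | os.PathLike) -> list[Path]:
    """Write frames as zero-padded PNGs (frame_000001.png, ...)."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames):
        p = out / f"frame_{i + 1:06d}.png"
        iio.imwrite(p, np.clip(np.asarray(frame), 0, 255).astype(np.uint8))
        paths.append(p)
    return paths
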