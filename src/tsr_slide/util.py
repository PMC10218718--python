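"""Small shared helpers: seed derivation and patch preprocessing."""

from __future__ import annotations

import zlib

import numpy as np


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31, derived from a global seed.

    Stage names are hashed (CRC32) and mixed with the global seed so stages
    never share a stream and reruns are reproducible from one integer.
    """
    return int((int(seed) * 0x9E3779B1 + zlib.crc32(stage.encode())) % (2**31))


def downsample_patches(patches: np.ndarray, target_hw: int = 32) -> np.ndarray:
    """Downsample (N, S, S, 3) patches to (N, t, t, 3) floats in [-0.5, 0.5].

    Block-averaging is used when S is a multiple of the target (the 224 -> 32
    fast path); other sizes fall back to a bilinear resize.
    """
    patches = np.asarray(patches, dtype=np.float64)
    n, s = patches.shape[0], patches.shape[1]
    if patches.ndim != 4 or patches.shape[1] != patches.shape[2] or patches.shape[3] != 3:
        raise ValueError(f"expected (N, S, S, 3) patches, got {patches.shape}")
    if s == target_hw:
        small = patches
    elif s % target_hw == 0:
        b = s // target_hw
        small = patches.reshape(n, target_hw, b, target_hw, b, 3).mean(axis=(2, 4))
    else:
        from skimage.transform import resize

        small = np.stack(
            [
                resize(p, (target_hw, target_hw, 3), order=1, anti_aliasing=True,
                       preserve_range=True)
                for p in patches
            ]
        )
    return (small / 255.0 - 0.5).astype(np.float64)
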