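"""Independent brute-force reference implementations used only by tests."""

from __future__ import annotations

import numpy as np


def flood_fill_label(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """Exhaustive 8-connected flood fill, labels in row-major discovery order."""
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=int)
    nxt = 0
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            if not mask[i, j] or labels[i, j]:
                continue
            nxt += 1
            stack = [(i, j)]
            labels[i, j] = nxt
            while stack:
                a, b = stack.pop()
                for da in (-1, 0, 1):
                    for db in (-1, 0, 1):
                        x, y = a + da, b + db
                        if (0 <= x < mask.shape[0] and 0 <= y < mask.shape[1]
                                and mask[x, y] and not labels[x, y]):
                            labels[x, y] = nxt
                            stack.append((x, y))
    return labels, nxt


def brute_force_tmap(power: np.ndarray, is_a: np.ndarray) -> np.ndarray:
    """Naive per-pixel pooled-variance two-sample t over the trial axis."""
    f, t, _ = power.shape
    out = np.empty((f, t))
    a = power[:, :, is_a]
    b = power[:, :, ~is_a]
    na, nb = a.shape[2], b.shape[2]
    for i in range(f):
        for j in range(t):
            xa, xb = a[i, j], b[i, j]
            sp2 = ((na - 1) * xa.var(ddof=1) + (nb - 1) * xb.var(ddof=1)) / (na + nb - 2)
            out[i, j] = (xa.mean() - xb.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    return out


def partial_corr_recursive(x, y, z) -> float:
    """First-order partial correlation via the closed-form recursion
    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))."""
    def r(u, v):
        u = np.asarray(u, float) - np.mean(u)
        v = np.asarray(v, float) - np.mean(v)
        return float(u @ v / np.sqrt((u @ u) * (v @ v)))

    rxy, rxz, ryz = r(x, y), r(x, z), r(y, z)
    return (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))


def welch_band_db(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    """Mean Hann-periodogram band power of segments (rows of x), in dB.

    Interior band bins only (2 bins inset from each edge) to keep window
    main-lobe leakage out of the measurement."""
    from scipy.signal import periodogram

    f, p = periodogram(x, fs=fs, window="hann", axis=-1)
    dfreq = f[1] - f[0]
    sel = (f >= band[0] + 2 * dfreq) & (f <= band[1] - 2 * dfreq)
    return 10.0 * np.log10(p[..., sel].mean())
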