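"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain nested loops over voxels so it can be
checked by eye; none of it shares code with the package's vectorized
builders.
"""

from __future__ import annotations

import numpy as np

OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]

DIRECTIONS_13 = [d for d in OFFSETS_26 if d > (0, 0, 0)]


def glcm_brute(levels: np.ndarray, distance: int = 1) -> np.ndarray:
    """Normalized symmetric GLCM by looping over every voxel pair."""
    ng = int(levels.max())
    counts = np.zeros((ng, ng))
    shape = levels.shape
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if levels[x, y, z] == 0:
                    continue
                for dx, dy, dz in OFFSETS_26:
                    nx, ny, nz = x + dx * distance, y + dy * distance, z + dz * distance
                    if not (0 <= nx < shape[0] and 0 <= ny < shape[1] and 0 <= nz < shape[2]):
                        continue
                    if levels[nx, ny, nz] == 0:
                        continue
                    counts[levels[x, y, z] - 1, levels[nx, ny, nz] - 1] += 1
    total = counts.sum()
    return counts / total if total else counts


def runs_brute(levels: np.ndarray, d) -> list[tuple[int, int]]:
    """All (level, run length) pairs along direction d, by line following."""
    shape = levels.shape
    runs = []
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                lev = levels[x, y, z]
                if lev == 0:
                    continue
                px, py, pz = x - d[0], y - d[1], z - d[2]
                if (
                    0 <= px < shape[0]
                    and 0 <= py < shape[1]
                    and 0 <= pz < shape[2]
                    and levels[px, py, pz] == lev
                ):
                    continue  # not a run start
                length = 1
                nx, ny, nz = x + d[0], y + d[1], z + d[2]
                while (
                    0 <= nx < shape[0]
                    and 0 <= ny < shape[1]
                    and 0 <= nz < shape[2]
                    and levels[nx, ny, nz] == lev
                ):
                    length += 1
                    nx, ny, nz = nx + d[0], ny + d[1], nz + d[2]
                runs.append((int(lev), length))
    return runs


def zones_brute(levels: np.ndarray) -> list[tuple[int, int]]:
    """All (level, zone size) pairs via 26-connected flood fill."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                lev = levels[x, y, z]
                if lev == 0 or seen[x, y, z]:
                    continue
                stack = [(x, y, z)]
                seen[x, y, z] = True
                size = 0
                while stack:
                    cx, cy, cz = stack.pop()
                    size += 1
                    for dx, dy, dz in OFFSETS_26:
                        nx, ny, nz = cx + dx, cy + dy, cz + dz
                        if (
                            0 <= nx < shape[0]
                            and 0 <= ny < shape[1]
                            and 0 <= nz < shape[2]
                            and not seen[nx, ny, nz]
                            and levels[nx, ny, nz] == lev
                        ):
                            seen[nx, ny, nz] = True
                            stack.append((nx, ny, nz))
                zones.append((int(lev), size))
    return zones


def ngtdm_brute(levels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(s, n) arrays over levels 1..max by explicit neighborhood loops."""
    ng = int(levels.max())
    s = np.zeros(ng)
    n = np.zeros(ng)
    shape = levels.shape
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                lev = levels[x, y, z]
                if lev == 0:
                    continue
                nb = []
                for dx, dy, dz in OFFSETS_26:
                    nx, ny, nz = x + dx, y + dy, z + dz
                    if (
                        0 <= nx < shape[0]
                        and 0 <= ny < shape[1]
                        and 0 <= nz < shape[2]
                        and levels[nx, ny, nz] > 0
                    ):
                        nb.append(levels[nx, ny, nz])
                if not nb:
                    continue
                s[lev - 1] += abs(lev - sum(nb) / len(nb))
                n[lev - 1] += 1
    return s, n


def separable_conv_brute(data: np.ndarray, kx, ky, kz) -> np.ndarray:
    """Direct-summation separable correlation with mirror boundary."""

    def mirror(i, n):
        # scipy 'mirror' mode: d c b | a b c d | c b a
        period = 2 * n - 2 if n > 1 else 1
        i = abs(i) % period
        return period - i if i >= n else i

    def corr_axis(arr, k, axis):
        arr = np.moveaxis(arr, axis, 0)
        out = np.zeros_like(arr, dtype=float)
        half = len(k) // 2
        n = arr.shape[0]
        for i in range(n):
            for t, w in enumerate(k):
                out[i] += w * arr[mirror(i + t - half, n)]
        return np.moveaxis(out, 0, axis)

    out = data.astype(float)
    for k, axis in ((kx, 0), (ky, 1), (kz, 2)):
        out = corr_axis(out, np.asarray(k, float), axis)
    return out


def haar_band_brute(data: np.ndarray, band: str) -> np.ndarray:
    """Undecimated 2-tap Haar sub-band with edge-replicated last sample."""

    def pair(arr, axis, high):
        arr = np.moveaxis(arr, axis, 0)
        out = np.zeros_like(arr, dtype=float)
        n = arr.shape[0]
        for i in range(n):
            nxt = arr[min(i + 1, n - 1)]
            out[i] = 0.5 * (arr[i] - nxt) if high else 0.5 * (arr[i] + nxt)
        return np.moveaxis(out, 0, axis)

    out = data.astype(float)
    for axis, letter in enumerate(band):
        out = pair(out, axis, letter == "H")
    return out


def lacunarity_brute(occupancy: np.ndarray, b: int) -> float:
    """Gliding-box lacunarity by explicit box sweep."""
    shape = occupancy.shape
    masses = []
    for x in range(shape[0] - b + 1):
        for y in range(shape[1] - b + 1):
            for z in range(shape[2] - b + 1):
                masses.append(int(occupancy[x : x + b, y : y + b, z : z + b].sum()))
    masses = np.asarray(masses, float)
    if masses.size == 0 or masses.mean() == 0:
        return float("nan")
    return float(1.0 + masses.var() / masses.mean() ** 2)
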