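"""Texture-matrix families: GLCM, GLRLM, GLSZM, GLDM.

All families operate on a discretized :class:`LabelImage`. Pair- and
run-based families use distance 1 along the four 2D directions
(0, 45, 90, 135 degrees) and report the per-direction feature average, so the
feature set is invariant under 90-degree rotations. Zones and dependences use
8-connectivity. Gray-level values entering the formulas are the integer
labels themselves; normalizers written ``Ng`` use the discretization's bin
count (the texture-matrix dimension).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..exceptions import TooFewPixelsError
from .discretize import LabelImage

# (dr, dc) offsets for 0, 45, 90, 135 degrees in array coordinates
DIRECTIONS: tuple[tuple[int, int], ...] = ((0, 1), (1, 1), (1, 0), (1, -1))

EIGHT_CONN = np.ones((3, 3), dtype=int)

GLCM_FEATURE_NAMES: tuple[str, ...] = (
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointAverage",
    "JointEnergy",
    "JointEntropy",
    "MCC",
    "MaximumProbability",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
)

GLRLM_FEATURE_NAMES: tuple[str, ...] = (
    "ShortRunEmphasis",
    "LongRunEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "GrayLevelVariance",
    "RunVariance",
    "RunEntropy",
    "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)

GLSZM_FEATURE_NAMES: tuple[str, ...] = (
    "SmallAreaEmphasis",
    "LargeAreaEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "ZonePercentage",
    "GrayLevelVariance",
    "ZoneVariance",
    "ZoneEntropy",
    "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)

GLDM_FEATURE_NAMES: tuple[str, ...] = (
    "SmallDependenceEmphasis",
    "LargeDependenceEmphasis",
    "GrayLevelNonUniformity",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "GrayLevelVariance",
    "DependenceVariance",
    "DependenceEntropy",
    "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)

_EPS = np.finfo(np.float64).tiny


def _require_pixels(li: LabelImage, n: int = 2) -> None:
    if li.n_pixels < n:
        raise TooFewPixelsError(f"texture features need >= {n} in-mask pixels")


def _shifted_pairs(li: LabelImage, direction: tuple[int, int]):
    """Label pairs (a, b) at offset ``direction`` with both pixels in-mask."""
    dr, dc = direction
    lab, m = li.labels, li.mask
    nr, nc = lab.shape
    r0, r1 = max(0, -dr), min(nr, nr - dr)
    c0, c1 = max(0, -dc), min(nc, nc - dc)
    a = lab[r0:r1, c0:c1]
    b = lab[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    va = m[r0:r1, c0:c1] & m[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    return a[va], b[va]


# ----------------------------------------------------------------------------- GLCM


def glcm_matrix(li: LabelImage, direction: tuple[int, int]) -> np.ndarray:
    """Symmetric gray-level co-occurrence counts at distance 1."""
    a, b = _shifted_pairs(li, direction)
    nb = li.n_bins
    counts = np.zeros((nb, nb), dtype=np.float64)
    np.add.at(counts, (a - 1, b - 1), 1.0)
    return counts + counts.T


def glcm_features_single(P: np.ndarray) -> dict[str, float]:
    """Co-occurrence features of one (already symmetric) count matrix."""
    return _glcm_features_single(P)


def _glcm_features_single(P: np.ndarray) -> dict[str, float]:
    total = P.sum()
    if total == 0:
        raise TooFewPixelsError("no valid pixel pair for GLCM")
    p = P / total
    nb = p.shape[0]
    i = np.arange(1, nb + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    present = px > 0
    ng = int(present.sum())
    mu_x = float((i * px).sum())
    sig_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))

    k_diff = np.arange(0, nb, dtype=np.float64)
    p_diff = np.zeros(nb)
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), p.ravel())
    k_sum = np.arange(2, 2 * nb + 1, dtype=np.float64)
    p_sum = np.zeros(2 * nb - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel() - 2, p.ravel())

    def ent(q):
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum())

    hx = ent(px)
    hxy = ent(p.ravel())
    pxpy = np.outer(px, px)
    nz = (p > 0) & (pxpy > 0)
    hxy1 = float(-(p[nz] * np.log2(pxpy[nz])).sum())
    nz2 = pxpy > 0
    hxy2 = float(-(pxpy[nz2] * np.log2(pxpy[nz2])).sum())

    da = float((k_diff * p_diff).sum())
    if sig_x > 0:
        corr = float(((ii * jj * p).sum() - mu_x * mu_x) / (sig_x * sig_x))
    else:
        corr = 1.0

    # maximal correlation coefficient: sqrt of the 2nd eigenvalue of Q
    if ng > 1:
        psub = p[np.ix_(present, present)]
        pxs = px[present]
        Q = (psub / pxs[:, None]) @ (psub / pxs[None, :]).T
        ev = np.sort(np.real(np.linalg.eigvals(Q)))
        mcc = float(np.sqrt(max(ev[-2], 0.0)))
    else:
        mcc = 1.0

    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(1.0 - np.exp(-2.0 * (hxy2 - hxy)), 0.0)))

    diff2 = (ii - jj) ** 2
    absdiff = np.abs(ii - jj)
    offdiag = diff2 > 0
    return {
        "Autocorrelation": float((ii * jj * p).sum()),
        "ClusterProminence": float(((ii + jj - 2 * mu_x) ** 4 * p).sum()),
        "ClusterShade": float(((ii + jj - 2 * mu_x) ** 3 * p).sum()),
        "ClusterTendency": float(((ii + jj - 2 * mu_x) ** 2 * p).sum()),
        "Contrast": float((diff2 * p).sum()),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": ent(p_diff),
        "DifferenceVariance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "Id": float((p / (1.0 + absdiff)).sum()),
        "Idm": float((p / (1.0 + diff2)).sum()),
        "Idmn": float((p / (1.0 + diff2 / nb**2)).sum()),
        "Idn": float((p / (1.0 + absdiff / nb)).sum()),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": float((p[offdiag] / diff2[offdiag]).sum()),
        "JointAverage": mu_x,
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(p.max()),
        "SumAverage": float((k_sum * p_sum).sum()),
        "SumEntropy": ent(p_sum),
        "SumSquares": float(((ii - mu_x) ** 2 * p).sum()),
    }


def glcm_features(li: LabelImage) -> dict[str, float]:
    """Direction-averaged co-occurrence features (24 values)."""
    _require_pixels(li)
    mats = [glcm_matrix(li, d) for d in DIRECTIONS]
    per_dir = [_glcm_features_single(P) for P in mats if P.sum() > 0]
    if not per_dir:
        raise TooFewPixelsError("no direction yields a valid pixel pair")
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLCM_FEATURE_NAMES}


# ----------------------------------------------------------------------------- GLRLM


def _lines(lab: np.ndarray, direction: tuple[int, int]) -> list[np.ndarray]:
    """All maximal scan lines of the array along ``direction`` (labels only)."""
    if direction == (0, 1):
        return [lab[r] for r in range(lab.shape[0])]
    if direction == (1, 0):
        return [lab[:, c] for c in range(lab.shape[1])]
    if direction == (1, 1):
        return [
            np.diagonal(lab, offset=o)
            for o in range(-lab.shape[0] + 1, lab.shape[1])
        ]
    if direction == (1, -1):
        fl = lab[:, ::-1]
        return [
            np.diagonal(fl, offset=o)
            for o in range(-fl.shape[0] + 1, fl.shape[1])
        ]
    raise ValueError(f"unsupported direction {direction}")


def glrlm_matrix(li: LabelImage, direction: tuple[int, int]) -> np.ndarray:
    """Run-length counts P[i, l]: gray level i+1, run length l+1.

    Out-of-mask pixels break runs; runs never cross the mask boundary.
    """
    masked = np.where(li.mask, li.labels, 0)
    lines = _lines(masked, direction)
    # sentinel-separated concatenation makes run extraction one vector pass
    big = np.concatenate([np.concatenate([ln, [0]]) for ln in lines])
    valid = big > 0
    prev = np.concatenate([[0], big[:-1]])
    starts = valid & (big != prev)
    run_id = np.cumsum(starts) - 1
    lengths = np.bincount(run_id[valid])
    run_labels = big[starts]
    maxlen = int(lengths.max()) if lengths.size else 0
    P = np.zeros((li.n_bins, max(maxlen, 1)), dtype=np.float64)
    np.add.at(P, (run_labels - 1, lengths - 1), 1.0)
    return P


def _rlm_style_features(P: np.ndarray, n_pixels: int, kind: str) -> dict[str, float]:
    """Shared feature arithmetic for run-length and size-zone matrices."""
    n_runs = P.sum()
    if n_runs == 0:
        raise TooFewPixelsError("empty texture matrix")
    i = np.arange(1, P.shape[0] + 1, dtype=np.float64)[:, None]
    l = np.arange(1, P.shape[1] + 1, dtype=np.float64)[None, :]
    p = P / n_runs
    mu_i = float((i * p).sum())
    mu_l = float((l * p).sum())
    pg = P.sum(axis=1)
    pl = P.sum(axis=0)
    p_nz = p[p > 0]
    feats = {
        "sre": float((P / l**2).sum() / n_runs),
        "lre": float((P * l**2).sum() / n_runs),
        "gln": float((pg**2).sum() / n_runs),
        "glnn": float((pg**2).sum() / n_runs**2),
        "rln": float((pl**2).sum() / n_runs),
        "rlnn": float((pl**2).sum() / n_runs**2),
        "rp": float(n_runs / n_pixels),
        "glv": float(((i - mu_i) ** 2 * p).sum()),
        "rv": float(((l - mu_l) ** 2 * p).sum()),
        "re": float(-(p_nz * np.log2(p_nz)).sum()),
        "lgl": float((P / i**2).sum() / n_runs),
        "hgl": float((P * i**2).sum() / n_runs),
        "slgl": float((P / (i**2 * l**2)).sum() / n_runs),
        "shgl": float((P * i**2 / l**2).sum() / n_runs),
        "llgl": float((P * l**2 / i**2).sum() / n_runs),
        "lhgl": float((P * i**2 * l**2).sum() / n_runs),
    }
    names = GLRLM_FEATURE_NAMES if kind == "run" else GLSZM_FEATURE_NAMES
    return dict(zip(names, feats.values()))


def glrlm_features(li: LabelImage) -> dict[str, float]:
    """Direction-averaged run-length features (16 values)."""
    _require_pixels(li)
    per_dir = [
        _rlm_style_features(glrlm_matrix(li, d), li.n_pixels, "run")
        for d in DIRECTIONS
    ]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLRLM_FEATURE_NAMES}


# ----------------------------------------------------------------------------- GLSZM


def glszm_matrix(li: LabelImage) -> np.ndarray:
    """Size-zone counts P[i, s]: 8-connected zones of gray level i+1, size s+1."""
    _require_pixels(li)
    masked = np.where(li.mask, li.labels, 0)
    levels = np.unique(masked[masked > 0])
    zones: list[tuple[int, int]] = []
    for lev in levels:
        comp, n_comp = ndimage.label(masked == lev, structure=EIGHT_CONN)
        if n_comp:
            sizes = np.bincount(comp.ravel())[1:]
            zones.extend((int(lev), int(s)) for s in sizes)
    max_size = max(s for _, s in zones)
    P = np.zeros((li.n_bins, max_size), dtype=np.float64)
    for lev, s in zones:
        P[lev - 1, s - 1] += 1.0
    return P


def glszm_features(li: LabelImage) -> dict[str, float]:
    """Size-zone features (16 values); zones are direction-free by construction."""
    return _rlm_style_features(glszm_matrix(li), li.n_pixels, "zone")


# ----------------------------------------------------------------------------- GLDM


def gldm_matrix(li: LabelImage) -> np.ndarray:
    """Dependence counts P[i, d]: gray level i+1 with d equal 8-neighbors.

    Dependence uses exact label equality (tolerance 0); neighbors outside the
    mask never count. Columns are raw neighbor counts d = 0..8.
    """
    _require_pixels(li)
    lab, m = li.labels, li.mask
    dep = np.zeros(lab.shape, dtype=np.int64)
    offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    nr, nc = lab.shape
    for dr, dc in offsets:
        r0, r1 = max(0, -dr), min(nr, nr - dr)
        c0, c1 = max(0, -dc), min(nc, nc - dc)
        same = (
            (lab[r0:r1, c0:c1] == lab[r0 + dr : r1 + dr, c0 + dc : c1 + dc])
            & m[r0:r1, c0:c1]
            & m[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        )
        dep[r0:r1, c0:c1] += same
    P = np.zeros((li.n_bins, 9), dtype=np.float64)
    np.add.at(P, (lab[m] - 1, dep[m]), 1.0)
    return P


def gldm_features(li: LabelImage) -> dict[str, float]:
    """Dependence-matrix features (14 values).

    The emphasis formulas weight by dependence *size* s = d + 1 (the center
    pixel counts itself), which keeps small-dependence emphases finite for
    isolated pixels.
    """
    P = gldm_matrix(li)
    nz_total = P.sum()
    i = np.arange(1, P.shape[0] + 1, dtype=np.float64)[:, None]
    s = np.arange(1, P.shape[1] + 1, dtype=np.float64)[None, :]  # d + 1
    p = P / nz_total
    mu_i = float((i * p).sum())
    mu_s = float((s * p).sum())
    pg = P.sum(axis=1)
    pd = P.sum(axis=0)
    p_nz = p[p > 0]
    return {
        "SmallDependenceEmphasis": float((P / s**2).sum() / nz_total),
        "LargeDependenceEmphasis": float((P * s**2).sum() / nz_total),
        "GrayLevelNonUniformity": float((pg**2).sum() / nz_total),
        "DependenceNonUniformity": float((pd**2).sum() / nz_total),
        "DependenceNonUniformityNormalized": float((pd**2).sum() / nz_total**2),
        "GrayLevelVariance": float(((i - mu_i) ** 2 * p).sum()),
        "DependenceVariance": float(((s - mu_s) ** 2 * p).sum()),
        "DependenceEntropy": float(-(p_nz * np.log2(p_nz)).sum()),
        "LowGrayLevelEmphasis": float((P / i**2).sum() / nz_total),
        "HighGrayLevelEmphasis": float((P * i**2).sum() / nz_total),
        "SmallDependenceLowGrayLevelEmphasis": float((P / (i**2 * s**2)).sum() / nz_total),
        "SmallDependenceHighGrayLevelEmphasis": float((P * i**2 / s**2).sum() / nz_total),
        "LargeDependenceLowGrayLevelEmphasis": float((P * s**2 / i**2).sum() / nz_total),
        "LargeDependenceHighGrayLevelEmphasis": float((P * i**2 * s**2).sum() / nz_total),
    }
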