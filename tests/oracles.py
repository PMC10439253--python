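"""Naive brute-force oracles: explicit pair/run/zone/neighborhood enumeration.

Everything here is written as plain loops from the feature definitions and is
deliberately independent of the package's vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np

DIRECTIONS = ((0, 1), (1, 1), (1, 0), (1, -1))


# --------------------------------------------------------------------- matrices


def bf_glcm_matrix(labels, mask, direction, n_bins):
    nr, nc = labels.shape
    dr, dc = direction
    P = np.zeros((n_bins, n_bins))
    for r in range(nr):
        for c in range(nc):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < nr and 0 <= c2 < nc and mask[r, c] and mask[r2, c2]:
                a, b = labels[r, c], labels[r2, c2]
                P[a - 1, b - 1] += 1
                P[b - 1, a - 1] += 1
    return P


def bf_runs(labels, mask, direction):
    """All (gray level, run length) pairs along one direction."""
    nr, nc = labels.shape
    dr, dc = direction
    runs = []
    for r in range(nr):
        for c in range(nc):
            rp, cp = r - dr, c - dc
            starts_line = not (0 <= rp < nr and 0 <= cp < nc)
            if not starts_line:
                continue
            rr, cc = r, c
            cur_label, cur_len = None, 0
            while 0 <= rr < nr and 0 <= cc < nc:
                if mask[rr, cc]:
                    if labels[rr, cc] == cur_label:
                        cur_len += 1
                    else:
                        if cur_label is not None:
                            runs.append((cur_label, cur_len))
                        cur_label, cur_len = labels[rr, cc], 1
                else:
                    if cur_label is not None:
                        runs.append((cur_label, cur_len))
                    cur_label, cur_len = None, 0
                rr += dr
                cc += dc
            if cur_label is not None:
                runs.append((cur_label, cur_len))
    return runs


def bf_glrlm_matrix(labels, mask, direction, n_bins):
    runs = bf_runs(labels, mask, direction)
    maxlen = max((l for _, l in runs), default=1)
    P = np.zeros((n_bins, maxlen))
    for g, l in runs:
        P[g - 1, l - 1] += 1
    return P


def bf_zones(labels, mask):
    """8-connected equal-label zones via BFS flood fill."""
    nr, nc = labels.shape
    seen = np.zeros_like(mask, dtype=bool)
    zones = []
    for r in range(nr):
        for c in range(nc):
            if not mask[r, c] or seen[r, c]:
                continue
            lev = labels[r, c]
            stack, size = [(r, c)], 0
            seen[r, c] = True
            while stack:
                rr, cc = stack.pop()
                size += 1
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        r2, c2 = rr + dr, cc + dc
                        if (
                            0 <= r2 < nr and 0 <= c2 < nc and not seen[r2, c2]
                            and mask[r2, c2] and labels[r2, c2] == lev
                        ):
                            seen[r2, c2] = True
                            stack.append((r2, c2))
            zones.append((lev, size))
    return zones


def bf_glszm_matrix(labels, mask, n_bins):
    zones = bf_zones(labels, mask)
    max_size = max(s for _, s in zones)
    P = np.zeros((n_bins, max_size))
    for g, s in zones:
        P[g - 1, s - 1] += 1
    return P


def bf_gldm_matrix(labels, mask, n_bins):
    nr, nc = labels.shape
    P = np.zeros((n_bins, 9))
    for r in range(nr):
        for c in range(nc):
            if not mask[r, c]:
                continue
            dep = 0
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if (dr, dc) == (0, 0):
                        continue
                    r2, c2 = r + dr, c + dc
                    if (
                        0 <= r2 < nr and 0 <= c2 < nc and mask[r2, c2]
                        and labels[r2, c2] == labels[r, c]
                    ):
                        dep += 1
            P[labels[r, c] - 1, dep] += 1
    return P


# --------------------------------------------------------------------- features


def bf_glcm_features(P):
    total = P.sum()
    p = P / total
    nb = p.shape[0]
    px = [sum(p[i, j] for j in range(nb)) for i in range(nb)]
    mu = sum((i + 1) * px[i] for i in range(nb))
    var = sum((i + 1 - mu) ** 2 * px[i] for i in range(nb))
    sig = math.sqrt(var)

    p_diff = [0.0] * nb
    p_sum = [0.0] * (2 * nb - 1)
    for i in range(nb):
        for j in range(nb):
            p_diff[abs(i - j)] += p[i, j]
            p_sum[i + j] += p[i, j]

    def ent(vals):
        return -sum(v * math.log2(v) for v in vals if v > 0)

    hx = ent(px)
    hxy = ent(p.ravel())
    hxy1 = -sum(
        p[i, j] * math.log2(px[i] * px[j])
        for i in range(nb) for j in range(nb)
        if p[i, j] > 0 and px[i] * px[j] > 0
    )
    hxy2 = -sum(
        px[i] * px[j] * math.log2(px[i] * px[j])
        for i in range(nb) for j in range(nb)
        if px[i] * px[j] > 0
    )

    da = sum(k * p_diff[k] for k in range(nb))
    if sig > 0:
        corr = (
            sum((i + 1) * (j + 1) * p[i, j] for i in range(nb) for j in range(nb))
            - mu * mu
        ) / (sig * sig)
    else:
        corr = 1.0

    present = [i for i in range(nb) if px[i] > 0]
    if len(present) > 1:
        Q = np.zeros((len(present), len(present)))
        for a, i in enumerate(present):
            for b, j in enumerate(present):
                Q[a, b] = sum(
                    p[i, k] * p[j, k] / (px[i] * px[k])
                    for k in present
                )
        ev = sorted(np.real(np.linalg.eigvals(Q)))
        mcc = math.sqrt(max(ev[-2], 0.0))
    else:
        mcc = 1.0

    f = {}
    f["Autocorrelation"] = sum((i + 1) * (j + 1) * p[i, j] for i in range(nb) for j in range(nb))
    for power, name in ((4, "ClusterProminence"), (3, "ClusterShade"), (2, "ClusterTendency")):
        f[name] = sum(
            (i + 1 + j + 1 - 2 * mu) ** power * p[i, j]
            for i in range(nb) for j in range(nb)
        )
    f["Contrast"] = sum((i - j) ** 2 * p[i, j] for i in range(nb) for j in range(nb))
    f["Correlation"] = corr
    f["DifferenceAverage"] = da
    f["DifferenceEntropy"] = ent(p_diff)
    f["DifferenceVariance"] = sum((k - da) ** 2 * p_diff[k] for k in range(nb))
    f["Id"] = sum(p[i, j] / (1 + abs(i - j)) for i in range(nb) for j in range(nb))
    f["Idm"] = sum(p[i, j] / (1 + (i - j) ** 2) for i in range(nb) for j in range(nb))
    f["Idmn"] = sum(p[i, j] / (1 + (i - j) ** 2 / nb**2) for i in range(nb) for j in range(nb))
    f["Idn"] = sum(p[i, j] / (1 + abs(i - j) / nb) for i in range(nb) for j in range(nb))
    f["Imc1"] = (hxy - hxy1) / hx if hx > 0 else 0.0
    f["Imc2"] = math.sqrt(max(1.0 - math.exp(-2.0 * (hxy2 - hxy)), 0.0))
    f["InverseVariance"] = sum(
        p[i, j] / (i - j) ** 2 for i in range(nb) for j in range(nb) if i != j
    )
    f["JointAverage"] = mu
    f["JointEnergy"] = sum(p[i, j] ** 2 for i in range(nb) for j in range(nb))
    f["JointEntropy"] = hxy
    f["MCC"] = mcc
    f["MaximumProbability"] = p.max()
    f["SumAverage"] = sum((k + 2) * p_sum[k] for k in range(2 * nb - 1))
    f["SumEntropy"] = ent(p_sum)
    f["SumSquares"] = sum((i + 1 - mu) ** 2 * p[i, j] for i in range(nb) for j in range(nb))
    return f


def _bf_rlm_features(P, n_pixels, names):
    n_runs = P.sum()
    ni, nl = P.shape
    p = P / n_runs
    mu_i = sum((i + 1) * p[i, l] for i in range(ni) for l in range(nl))
    mu_l = sum((l + 1) * p[i, l] for i in range(ni) for l in range(nl))
    pg = [sum(P[i, l] for l in range(nl)) for i in range(ni)]
    pl = [sum(P[i, l] for i in range(ni)) for l in range(nl)]
    vals = [
        sum(P[i, l] / (l + 1) ** 2 for i in range(ni) for l in range(nl)) / n_runs,
        sum(P[i, l] * (l + 1) ** 2 for i in range(ni) for l in range(nl)) / n_runs,
        sum(g**2 for g in pg) / n_runs,
        sum(g**2 for g in pg) / n_runs**2,
        sum(x**2 for x in pl) / n_runs,
        sum(x**2 for x in pl) / n_runs**2,
        n_runs / n_pixels,
        sum((i + 1 - mu_i) ** 2 * p[i, l] for i in range(ni) for l in range(nl)),
        sum((l + 1 - mu_l) ** 2 * p[i, l] for i in range(ni) for l in range(nl)),
        -sum(
            p[i, l] * math.log2(p[i, l])
            for i in range(ni) for l in range(nl) if p[i, l] > 0
        ),
        sum(P[i, l] / (i + 1) ** 2 for i in range(ni) for l in range(nl)) / n_runs,
        sum(P[i, l] * (i + 1) ** 2 for i in range(ni) for l in range(nl)) / n_runs,
        sum(P[i, l] / ((i + 1) ** 2 * (l + 1) ** 2) for i in range(ni) for l in range(nl)) / n_runs,
        sum(P[i, l] * (i + 1) ** 2 / (l + 1) ** 2 for i in range(ni) for l in range(nl)) / n_runs,
        sum(P[i, l] * (l + 1) ** 2 / (i + 1) ** 2 for i in range(ni) for l in range(nl)) / n_runs,
        sum(P[i, l] * (i + 1) ** 2 * (l + 1) ** 2 for i in range(ni) for l in range(nl)) / n_runs,
    ]
    return dict(zip(names, vals))


def bf_glrlm_features(labels, mask, n_bins, names):
    per_dir = [
        _bf_rlm_features(bf_glrlm_matrix(labels, mask, d, n_bins), mask.sum(), names)
        for d in DIRECTIONS
    ]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in names}


def bf_glszm_features(labels, mask, n_bins, names):
    return _bf_rlm_features(bf_glszm_matrix(labels, mask, n_bins), mask.sum(), names)


def bf_gldm_features(labels, mask, n_bins, names):
    P = bf_gldm_matrix(labels, mask, n_bins)
    total = P.sum()
    ni, nd = P.shape
    p = P / total
    mu_i = sum((i + 1) * p[i, d] for i in range(ni) for d in range(nd))
    mu_s = sum((d + 1) * p[i, d] for i in range(ni) for d in range(nd))
    pg = [sum(P[i, d] for d in range(nd)) for i in range(ni)]
    pd_ = [sum(P[i, d] for i in range(ni)) for d in range(nd)]
    vals = [
        sum(P[i, d] / (d + 1) ** 2 for i in range(ni) for d in range(nd)) / total,
        sum(P[i, d] * (d + 1) ** 2 for i in range(ni) for d in range(nd)) / total,
        sum(g**2 for g in pg) / total,
        sum(x**2 for x in pd_) / total,
        sum(x**2 for x in pd_) / total**2,
        sum((i + 1 - mu_i) ** 2 * p[i, d] for i in range(ni) for d in range(nd)),
        sum((d + 1 - mu_s) ** 2 * p[i, d] for i in range(ni) for d in range(nd)),
        -sum(
            p[i, d] * math.log2(p[i, d])
            for i in range(ni) for d in range(nd) if p[i, d] > 0
        ),
        sum(P[i, d] / (i + 1) ** 2 for i in range(ni) for d in range(nd)) / total,
        sum(P[i, d] * (i + 1) ** 2 for i in range(ni) for d in range(nd)) / total,
        sum(P[i, d] / ((i + 1) ** 2 * (d + 1) ** 2) for i in range(ni) for d in range(nd)) / total,
        sum(P[i, d] * (i + 1) ** 2 / (d + 1) ** 2 for i in range(ni) for d in range(nd)) / total,
        sum(P[i, d] * (d + 1) ** 2 / (i + 1) ** 2 for i in range(ni) for d in range(nd)) / total,
        sum(P[i, d] * (i + 1) ** 2 * (d + 1) ** 2 for i in range(ni) for d in range(nd)) / total,
    ]
    return dict(zip(names, vals))


def bf_glcm_features_averaged(labels, mask, n_bins, names):
    per_dir = []
    for d in DIRECTIONS:
        P = bf_glcm_matrix(labels, mask, d, n_bins)
        if P.sum() > 0:
            per_dir.append(bf_glcm_features(P))
    return {k: float(np.mean([f[k] for f in per_dir])) for k in names}


def linear_interp_1d(values, x):
    """Closed-form linear interpolation at fractional index x (clamped)."""
    x = min(max(x, 0.0), len(values) - 1.0)
    i0 = int(math.floor(x))
    i1 = min(i0 + 1, len(values) - 1)
    frac = x - i0
    return values[i0] * (1 - frac) + values[i1] * frac
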