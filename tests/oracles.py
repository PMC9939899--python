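"""Independent brute-force oracles used by the test suite.

Everything here is written as a direct, loop-based translation of the
defining formulas, deliberately sharing no code with the package.
"""

from __future__ import annotations

import math

import numpy as np


# --- dynamic transforms (direct translation of the definitions) -------------

def sd_naive(values):
    k = len(values)
    fbar = sum(values) / k
    return sum(abs(v - fbar) for v in values) / k


def dc_naive(values):
    fbar = sum(values) / len(values)
    if abs(fbar) < 1e-12:
        return 0.0
    return sd_naive(values) / abs(fbar)


def rcr_naive(values):
    k = len(values)
    out = {}
    for j in range(1, k + 1):
        for i in range(j + 1, k + 1):
            den = abs(values[i - 1])
            out[(j, i)] = 0.0 if den < 1e-12 else abs(values[j - 1] - values[i - 1]) / den
    return out


def racr_naive(values):
    k = len(values)
    fbar = sum(values) / k
    out = {}
    for j in range(1, k + 1):
        for i in range(j + 1, k + 1):
            out[(j, i)] = 0.0 if abs(fbar) < 1e-12 else abs(values[j - 1] - values[i - 1]) / abs(fbar)
    return out


def poly_naive(values, times, degree):
    """Least squares via the normal equations, solved with plain numpy."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    X = np.column_stack([t**m for m in range(degree + 1)])
    coef = np.linalg.solve(X.T @ X, X.T @ y)
    rss = float(np.sum((y - X @ coef) ** 2))
    return coef, rss


# --- ROC AUC by exhaustive pair counting ------------------------------------

def auc_pairs(scores, labels):
    scores = list(map(float, scores))
    labels = list(map(int, labels))
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


# --- GLCM by explicit pair counting -----------------------------------------

def glcm_counts(levels, mask, direction):
    """Symmetric co-occurrence counts by looping over every voxel."""
    nz, ny, nx = levels.shape
    dz, dy, dx = direction
    n_levels = int(levels[mask].max())
    P = np.zeros((n_levels, n_levels))
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x]:
                    continue
                z2, y2, x2 = z + dz, y + dy, x + dx
                if not (0 <= z2 < nz and 0 <= y2 < ny and 0 <= x2 < nx):
                    continue
                if not mask[z2, y2, x2]:
                    continue
                a, b = levels[z, y, x] - 1, levels[z2, y2, x2] - 1
                P[a, b] += 1
                P[b, a] += 1
    return P


def glcm_stats_naive(P):
    """GLCM statistics from a count matrix, by explicit double loops."""
    total = P.sum()
    p = P / total
    ng = p.shape[0]
    px = [sum(p[i][j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i][j] for i in range(ng)) for j in range(ng)]
    mux = sum((i + 1) * px[i] for i in range(ng))
    muy = sum((j + 1) * py[j] for j in range(ng))
    sigx = math.sqrt(sum((i + 1 - mux) ** 2 * px[i] for i in range(ng)))
    sigy = math.sqrt(sum((j + 1 - muy) ** 2 * py[j] for j in range(ng)))

    contrast = corr_num = ent = shade = prom = 0.0
    for i in range(ng):
        for j in range(ng):
            pij = p[i][j]
            contrast += (i - j) ** 2 * pij
            corr_num += (i + 1 - mux) * (j + 1 - muy) * pij
            if pij > 0:
                ent -= pij * math.log2(pij)
            shade += (i + j + 2 - mux - muy) ** 3 * pij
            prom += (i + j + 2 - mux - muy) ** 4 * pij
    correlation = corr_num / (sigx * sigy) if sigx * sigy > 0 else 1.0

    pdiff = [0.0] * ng
    for i in range(ng):
        for j in range(ng):
            pdiff[abs(i - j)] += p[i][j]
    diff_ent = -sum(q * math.log2(q) for q in pdiff if q > 0)

    idn = sum(p[i][j] / (1 + abs(i - j) / ng) for i in range(ng) for j in range(ng))
    idmn = sum(p[i][j] / (1 + (abs(i - j) / ng) ** 2) for i in range(ng) for j in range(ng))

    hx = -sum(q * math.log2(q) for q in px if q > 0)
    hy = -sum(q * math.log2(q) for q in py if q > 0)
    hxy1 = -sum(
        p[i][j] * math.log2(px[i] * py[j])
        for i in range(ng)
        for j in range(ng)
        if p[i][j] > 0 and px[i] * py[j] > 0
    )
    hxy2 = -sum(
        px[i] * py[j] * math.log2(px[i] * py[j])
        for i in range(ng)
        for j in range(ng)
        if px[i] * py[j] > 0
    )
    hmax = max(hx, hy)
    imc1 = (ent - hxy1) / hmax if hmax > 0 else 0.0
    imc2 = math.sqrt(max(0.0, 1 - math.exp(-2 * (hxy2 - ent)))) if hxy2 >= ent else 0.0

    Q = np.zeros((ng, ng))
    for i in range(ng):
        for j in range(ng):
            s = 0.0
            for k in range(ng):
                if px[i] > 0 and py[k] > 0:
                    s += p[i][k] * p[j][k] / (px[i] * py[k])
            Q[i, j] = s
    ev = sorted(np.real(np.linalg.eigvals(Q)), reverse=True)
    mcc = math.sqrt(max(0.0, ev[1])) if ng > 1 else 1.0

    return {
        "glcm_Contrast": contrast,
        "glcm_Correlation": correlation,
        "glcm_JointEntropy": ent,
        "glcm_DifferenceEntropy": diff_ent,
        "glcm_Idn": idn,
        "glcm_Idmn": idmn,
        "glcm_Imc1": imc1,
        "glcm_Imc2": imc2,
        "glcm_MCC": mcc,
        "glcm_ClusterShade": shade,
        "glcm_ClusterProminence": prom,
    }


# --- survival ----------------------------------------------------------------

def km_naive(times, events):
    """Product-limit estimator at each distinct event time."""
    order = np.argsort(times)
    t, e = np.asarray(times, float)[order], np.asarray(events, int)[order]
    out_t, out_s = [], []
    s = 1.0
    for ut in np.unique(t):
        at_risk = np.sum(t >= ut)
        d = np.sum((t == ut) & (e == 1))
        if d > 0:
            s *= 1 - d / at_risk
            out_t.append(float(ut))
            out_s.append(float(s))
    return out_t, out_s


def logrank_naive(t1, e1, t0, e0):
    """Two-group log-rank chi-square via the O-E / hypergeometric-variance
    sums; equals the Cox score test at beta=0 when event times are untied."""
    t = np.concatenate([t1, t0])
    e = np.concatenate([e1, e0]).astype(int)
    g = np.concatenate([np.ones(len(t1)), np.zeros(len(t0))]).astype(int)
    O = E = V = 0.0
    for ut in np.unique(t[e == 1]):
        at = t >= ut
        n = at.sum()
        n1 = (at & (g == 1)).sum()
        d = ((t == ut) & (e == 1)).sum()
        d1 = ((t == ut) & (e == 1) & (g == 1)).sum()
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = (O - E) ** 2 / V if V > 0 else 0.0
    return chi2
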