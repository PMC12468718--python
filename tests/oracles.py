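"""Independent nested-loop reference implementations used as test oracles.

Everything here is written for clarity over speed (explicit Python loops,
direct transcription of the defining formulas) and deliberately shares no
code with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# preprocessing references
# ---------------------------------------------------------------------------

def clahe_ref(img, tile_rows, tile_cols, clip_limit):
    """Loop-level CLAHE: per-tile clipped equalisation + bilinear blending."""
    img = np.asarray(img, dtype=np.int64)
    h, w = img.shape
    th = math.ceil(h / tile_rows)
    tw = math.ceil(w / tile_cols)
    padded = np.pad(img, ((0, th * tile_rows - h), (0, tw * tile_cols - w)), mode="reflect")
    mn = th * tw
    clip = clip_limit * mn / 256

    maps = {}
    for r in range(tile_rows):
        for c in range(tile_cols):
            tile = padded[r * th:(r + 1) * th, c * tw:(c + 1) * tw]
            hist = [0.0] * 256
            for val in tile.ravel():
                hist[val] += 1.0
            excess = sum(max(b - clip, 0.0) for b in hist)
            if excess > 0:
                hist = [min(b, clip) + excess / 256 for b in hist]
            m = []
            cum = 0.0
            for b in hist:
                cum += b
                m.append(min(max(math.floor((255 / mn) * cum + 0.5), 0), 255))
            maps[(r, c)] = m

    hp, wp = padded.shape
    out = np.zeros((hp, wp), dtype=np.int64)
    for i in range(hp):
        ty = min(max((i - (th - 1) / 2) / th, 0.0), tile_rows - 1.0)
        y0 = int(math.floor(ty))
        y1 = min(y0 + 1, tile_rows - 1)
        fy = ty - y0
        for j in range(wp):
            tx = min(max((j - (tw - 1) / 2) / tw, 0.0), tile_cols - 1.0)
            x0 = int(math.floor(tx))
            x1 = min(x0 + 1, tile_cols - 1)
            fx = tx - x0
            v = padded[i, j]
            val = (1.0 - fy) * ((1.0 - fx) * maps[(y0, x0)][v] + fx * maps[(y0, x1)][v]) \
                + fy * ((1.0 - fx) * maps[(y1, x0)][v] + fx * maps[(y1, x1)][v])
            out[i, j] = min(max(math.floor(val + 0.5), 0), 255)
    return out[:h, :w].astype(np.uint8)


def nlm_ref(img, patch_radius, search_radius, h):
    """Exhaustive double-loop non-local means on [0,1]-normalised intensities."""
    img = np.asarray(img, dtype=np.float64) / 255.0
    hi, wi = img.shape
    pr, sr = patch_radius, search_radius
    pad = pr + sr
    big = np.pad(img, pad, mode="reflect")
    out = np.zeros((hi, wi))
    for i in range(hi):
        for j in range(wi):
            ci, cj = i + pad, j + pad
            num = 0.0
            den = 0.0
            for dy in range(-sr, sr + 1):
                for dx in range(-sr, sr + 1):
                    d2 = 0.0
                    for u in range(-pr, pr + 1):
                        for v in range(-pr, pr + 1):
                            diff = big[ci + u, cj + v] - big[ci + dy + u, cj + dx + v]
                            d2 += diff * diff
                    wgt = math.exp(-d2 / (2.0 * h * h))
                    num += wgt * big[ci + dy, cj + dx]
                    den += wgt
            out[i, j] = 255.0 * num / den
    return np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)


def kuwahara_ref(img, window_size, mode="standard", linear_temp=8.0):
    """Per-pixel quadrant enumeration with exact integer variance criterion."""
    img = np.asarray(img, dtype=np.int64)
    hi, wi = img.shape
    r = window_size // 2
    q = r + 1
    n = q * q
    big = np.pad(img, r, mode="reflect")
    out = np.zeros((hi, wi))
    # quadrant offsets relative to the centre pixel: NW, NE, SW, SE
    quads = [(-r, -r), (-r, 0), (0, -r), (0, 0)]
    for i in range(hi):
        for j in range(wi):
            ci, cj = i + r, j + r
            stats = []
            for oy, ox in quads:
                s1 = 0
                s2 = 0
                for u in range(q):
                    for v in range(q):
                        val = int(big[ci + oy + u, cj + ox + v])
                        s1 += val
                        s2 += val * val
                stats.append((n * s2 - s1 * s1, s1))
            if mode == "standard":
                best = 0
                for k in range(1, 4):
                    if stats[k][0] < stats[best][0]:
                        best = k
                out[i, j] = stats[best][1] / n
            else:
                weights = [(crit / (n * n) + 1e-6) ** (-linear_temp) for crit, _ in stats]
                num = 0.0
                den = 0.0
                for wk, (_, s1) in zip(weights, stats):
                    num = num + wk * (s1 / n)
                    den = den + wk
                out[i, j] = num / den
    return np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# attention references (channels-last (H, W, C) maps)
# ---------------------------------------------------------------------------

def gap_ref(fm):
    h, w, c = fm.shape
    out = np.zeros(c)
    for k in range(c):
        s = 0.0
        for i in range(h):
            for j in range(w):
                s += fm[i, j, k]
        out[k] = s / (h * w)
    return out


def conv1d_same_ref(vec, kernel):
    c = len(vec)
    k = len(kernel)
    p = k // 2
    out = np.zeros(c)
    for i in range(c):
        s = 0.0
        for j in range(k):
            idx = i + j - p
            if 0 <= idx < c:
                s += kernel[j] * vec[idx]
        out[i] = s
    return out


def aca_gate_ref(fm, kernel, alpha=1.0, gate="residual"):
    omega = np.tanh(alpha * conv1d_same_ref(gap_ref(fm), kernel))
    out = np.zeros_like(fm)
    h, w, c = fm.shape
    for i in range(h):
        for j in range(w):
            for k in range(c):
                g = (1.0 + omega[k]) if gate == "residual" else omega[k]
                out[i, j, k] = fm[i, j, k] * g
    return out


def fc_attention_ref(fm, ua, ub, alpha=1.0, gate="residual"):
    g = gap_ref(fm)
    hidden = np.zeros(ua.shape[1])
    for a in range(ua.shape[1]):
        hidden[a] = sum(g[i] * ua[i, a] for i in range(ua.shape[0]))
    raw = np.zeros(ub.shape[1])
    for b in range(ub.shape[1]):
        raw[b] = sum(hidden[a] * ub[a, b] for a in range(ub.shape[0]))
    omega = np.tanh(alpha * raw)
    out = np.array(fm, dtype=np.float64)
    for k in range(fm.shape[2]):
        gain = (1.0 + omega[k]) if gate == "residual" else omega[k]
        out[:, :, k] = fm[:, :, k] * gain
    return out


def conv2d_same_ref(plane, kernel):
    """Zero-padded same cross-correlation of a 2D plane with an odd kernel."""
    ph, pw = plane.shape
    k = kernel.shape[0]
    p = k // 2
    out = np.zeros((ph, pw))
    for i in range(ph):
        for j in range(pw):
            s = 0.0
            for u in range(k):
                for v in range(k):
                    y, x = i + u - p, j + v - p
                    if 0 <= y < ph and 0 <= x < pw:
                        s += kernel[u, v] * plane[y, x]
            out[i, j] = s
    return out


_BRANCH_AXIS = {"height-channel": 1, "width-channel": 0, "height-width": 2}


def dta_branch_ref(fm, branch, kernel, alpha=1.0):
    axis = _BRANCH_AXIS[branch]
    x_hat = np.moveaxis(np.asarray(fm, dtype=np.float64), axis, 0)
    r, a, b = x_hat.shape
    mx = np.zeros((a, b))
    av = np.zeros((a, b))
    for i in range(a):
        for j in range(b):
            vals = [x_hat[t, i, j] for t in range(r)]
            mx[i, j] = max(vals)
            av[i, j] = sum(vals) / r
    conv = conv2d_same_ref(mx, kernel[0]) + conv2d_same_ref(av, kernel[1])
    omega = np.tanh(alpha * conv)
    gated = np.zeros_like(x_hat)
    for t in range(r):
        gated[t] = x_hat[t] * omega
    return gated, omega


def dta_ref(fm, kernels, alpha=1.0):
    order = ["height-channel", "width-channel", "height-width"]
    if not isinstance(kernels, dict):
        kernels = dict(zip(order, kernels))
    acc = np.zeros_like(np.asarray(fm, dtype=np.float64))
    for branch in order:
        gated, _ = dta_branch_ref(fm, branch, kernels[branch], alpha)
        acc += np.moveaxis(gated, 0, _BRANCH_AXIS[branch])
    return acc / 3.0


# ---------------------------------------------------------------------------
# metric reference
# ---------------------------------------------------------------------------

def pixel_metrics_ref(pred, true, n_classes):
    """Per-pixel brute-force one-vs-rest metric computation."""
    pred = np.asarray(pred).ravel()
    true = np.asarray(true).ravel()
    out = {}
    for c in range(n_classes):
        tp = tn = fp = fn = 0
        for p, t in zip(pred, true):
            if t == c and p == c:
                tp += 1
            elif t != c and p != c:
                tn += 1
            elif t != c and p == c:
                fp += 1
            else:
                fn += 1
        acc = (tp + tn) / (tp + tn + fp + fn)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        iou = tp / (tp + fp + fn) if tp + fp + fn else 0.0
        dsc = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
        out[c] = {"tp": tp, "tn": tn, "fp": fp, "fn": fn, "accuracy": acc,
                  "precision": prec, "recall": rec, "f1": f1, "iou": iou,
                  "dsc": dsc, "support": tp + fn}
    return out
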