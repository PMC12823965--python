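"""Independent brute-force oracles used by the test suite.

Everything here is a direct, readable transcription of each statistic's
definition (double loops, exhaustive scans), deliberately sharing no code
with the package implementation.
"""

import numpy as np


def apen_brute(x, m=2, r=None):
    """Approximate entropy by explicit template double loop (Pincus)."""
    x = np.asarray(x, float)
    n = len(x)
    if r is None:
        r = 0.2 * x.std()

    def phi(mm):
        templates = [x[i:i + mm] for i in range(n - mm + 1)]
        logs = []
        for t1 in templates:
            c = sum(1 for t2 in templates if np.max(np.abs(t1 - t2)) <= r)
            logs.append(np.log(c / len(templates)))
        return np.mean(logs)

    return phi(m) - phi(m + 1)


def fuzzyen_brute(x, m=2, r=None, nexp=2.0):
    """Fuzzy entropy by explicit pairwise membership sums (Chen)."""
    x = np.asarray(x, float)
    n = len(x)
    if r is None:
        r = 0.2 * x.std()

    def phi(mm):
        n_t = n - m
        templates = [x[i:i + mm] - np.mean(x[i:i + mm]) for i in range(n_t)]
        total = 0.0
        for i in range(n_t):
            for j in range(n_t):
                if i == j:
                    continue
                d = np.max(np.abs(templates[i] - templates[j]))
                total += np.exp(-((d / r) ** nexp))
        return total / (n_t * (n_t - 1))

    return np.log(phi(m)) - np.log(phi(m + 1))


def renyi_ip_brute(x, sigma):
    """Information potential by explicit O(P^2) kernel sum."""
    x = np.asarray(x, float)
    total = 0.0
    for yj in x:
        for yk in x:
            total += np.exp(-((yk - yj) ** 2) / (2 * sigma ** 2)) / (
                sigma * np.sqrt(2 * np.pi))
    return total / len(x) ** 2


def boundaries_brute(mag, n_modes):
    """Spectral segmentation by exhaustive candidate sort and argmin scans.

    Returns the sorted unique boundary bins including 0 and len(mag)
    (the pi edge), mirroring the half-open partition convention.
    """
    mag = np.asarray(mag, float)
    n = len(mag)
    candidates = [0, n - 1]
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and mag[j + 1] == mag[i]:
            j += 1
        if mag[i] > mag[i - 1] and j + 1 < n and mag[i] > mag[j + 1]:
            candidates.append(i)
        i = j + 1
    candidates = sorted(set(candidates))
    ranked = sorted(candidates, key=lambda b: (-mag[b], b))
    top = sorted(ranked[:min(n_modes, len(ranked))])
    bounds = [0]
    for a, b in zip(top[:-1], top[1:]):
        if b - a > 1:
            seg = mag[a + 1:b]
            bounds.append(a + 1 + int(np.argmin(seg)))
        else:
            bounds.append(b)
    bounds.append(n)
    return sorted(set(bounds))


def confusion_brute(y_true, y_pred, positive):
    """Counts and percent metrics straight from (truth, prediction) pairs."""
    tp = sum(1 for t, p in zip(y_true, y_pred) if t == positive and p == positive)
    fn = sum(1 for t, p in zip(y_true, y_pred) if t == positive and p != positive)
    tn = sum(1 for t, p in zip(y_true, y_pred) if t != positive and p != positive)
    fp = sum(1 for t, p in zip(y_true, y_pred) if t != positive and p == positive)
    total = tp + fn + tn + fp
    out = {"tp": tp, "fn": fn, "tn": tn, "fp": fp,
           "Ac": 100 * (tp + tn) / total}
    out["Se"] = 100 * tp / (tp + fn) if tp + fn else None
    out["Sp"] = 100 * tn / (tn + fp) if tn + fp else None
    out["Pr"] = 100 * tp / (tp + fp) if tp + fp else None
    if out["Se"] is not None and out["Pr"] is not None and out["Se"] + out["Pr"] > 0:
        out["Fs"] = 2 * out["Pr"] * out["Se"] / (out["Pr"] + out["Se"])
    else:
        out["Fs"] = None
    return out


def auc_rank_brute(scores, y, positive):
    """AUC as the Mann-Whitney pair probability, ties counted half."""
    scores = np.asarray(scores, float)
    pos = np.asarray([lbl == positive for lbl in y])
    wins = 0.0
    for sp in scores[pos]:
        for sn in scores[~pos]:
            wins += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return wins / (pos.sum() * (~pos).sum())


def segment_count_brute(n_samples, fs, window_s, overlap_s):
    """Enumerate window start positions one by one."""
    win = int(round(window_s * fs))
    step = int(round((window_s - overlap_s) * fs))
    count = 0
    start = 0
    while start + win <= n_samples:
        count += 1
        start += step
    return count
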