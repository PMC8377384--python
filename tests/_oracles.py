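"""Independent literal-summation oracles for the encoders, metrics and the
single boosting step. These deliberately use plain loops and dictionaries,
sharing no code with the library paths they check."""

import math

from ppiboost.properties import (
    physicochemical_properties,
    pseaac_properties,
    rsiv_properties,
)
from ppiboost.seqio import AMINO_ACIDS
from ppiboost.encoders import REDUCED_CLASSES


def _norm_dicts(tables):
    out = []
    for t in tables:
        d = dict(t.normalized)
        d["X"] = 0.0
        out.append(d)
    return out


def pseaac_bruteforce(seq, lam, w=0.05):
    """Type-1 pseudo amino acid composition by literal summation."""
    props = _norm_dicts(pseaac_properties())
    L = len(seq)

    def theta_pair(a, b):
        return sum((p[a] - p[b]) ** 2 for p in props) / len(props)

    thetas = []
    for k in range(1, lam + 1):
        total = 0.0
        for i in range(L - k):
            total += theta_pair(seq[i], seq[i + k])
        thetas.append(total / (L - k))
    counts = [sum(1 for r in seq if r == a) for a in AMINO_ACIDS]
    denom = sum(counts) + w * sum(thetas)
    return [c / denom for c in counts] + [w * t / denom for t in thetas]


def psepssm_bruteforce(scores, xi):
    """PsePSSM by double loops: row standardization, column means, lag terms."""
    L = len(scores)
    std_rows = []
    for row in scores:
        mu = sum(row) / 20.0
        var = sum((v - mu) ** 2 for v in row) / 20.0
        sd = math.sqrt(var)
        std_rows.append([(v - mu) / sd if sd > 0 else 0.0 for v in row])
    feats = []
    for j in range(20):
        feats.append(sum(std_rows[i][j] for i in range(L)) / L)
    for g in range(1, xi + 1):
        for j in range(20):
            total = 0.0
            for i in range(L - g):
                total += (std_rows[i][j] - std_rows[i + g][j]) ** 2
            feats.append(total / (L - g))
    return feats


def rsiv_bruteforce(seq):
    """Reduced sequence and index vectors by explicit counting."""
    props = _norm_dicts(rsiv_properties())
    L = len(seq)
    std = [r for r in seq if r != "X"]
    n_std = len(std)
    feats = []
    for p in props:
        for a in AMINO_ACIDS:
            freq = sum(1 for r in std if r == a) / n_std
            feats.append(p[a] * freq)
    cls = {}
    for idx, group in enumerate(REDUCED_CLASSES):
        for a in group:
            cls[a] = idx
    classes = [cls.get(r) for r in seq]
    for c in range(7):
        feats.append(sum(1 for x in classes if x == c) / n_std)
    dipep = [[0.0] * 7 for _ in range(7)]
    for i in range(L - 1):
        c1, c2 = classes[i], classes[i + 1]
        if c1 is not None and c2 is not None:
            dipep[c1][c2] += 1
    for c1 in range(7):
        for c2 in range(7):
            feats.append(dipep[c1][c2] / (L - 1))
    for c1 in range(7):
        for c2 in range(c1 + 1, 7):
            feats.append((dipep[c1][c2] + dipep[c2][c1]) / (L - 1))
    return feats


def ad_bruteforce(seq, lag):
    """Moreau-Broto, Moran and Geary autocorrelation by literal summation."""
    props = _norm_dicts(physicochemical_properties())
    L = len(seq)
    feats = []
    for family in ("mba", "ma", "ga"):
        for p in props:
            vals = [p[r] for r in seq]
            pbar = sum(vals) / L
            ss = sum((v - pbar) ** 2 for v in vals)
            if ss <= 1e-20 * max(1.0, sum(v * v for v in vals)):
                ss = 0.0  # constant signal up to float rounding
            for d in range(1, lag + 1):
                if family == "mba":
                    feats.append(sum(vals[i] * vals[i + d] for i in range(L - d)) / (L - d))
                elif family == "ma":
                    if ss == 0:
                        feats.append(0.0)
                    else:
                        num = sum(
                            (vals[i] - pbar) * (vals[i + d] - pbar) for i in range(L - d)
                        ) / (L - d)
                        feats.append(num / (ss / L))
                else:
                    if ss == 0:
                        feats.append(0.0)
                    else:
                        num = sum(
                            (vals[i] - vals[i + d]) ** 2 for i in range(L - d)
                        ) / (2 * (L - d))
                        feats.append(num / (ss / (L - 1)))
    return feats


def auroc_pair_counting(y, scores):
    """AUROC as the normalized Mann-Whitney U by brute-force pair counting."""
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == 0]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def metrics_closed_form(tp, tn, fp, fn):
    """Recall, precision, ACC and MCC straight from the closed forms."""
    n = tp + tn + fp + fn
    recall = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    acc = (tp + tn) / n
    den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / den if den else 0.0
    return recall, precision, acc, mcc


def gtb_one_step(X, y, learning_rate):
    """One boosting iteration with a depth-1 tree, written out literally.

    Initial score F0 is the log-odds of the class prior. The stump is found
    by exhaustively minimizing the squared error of the deviance residuals
    over all (feature, threshold) splits; each leaf takes the one-step
    Newton value sum(residual) / sum(p(1-p)); the returned scores are
    F0 + learning_rate * leaf_value per sample.
    """
    n = len(y)
    p0 = sum(y) / n
    f0 = math.log(p0 / (1 - p0))
    residual = [yi - p0 for yi in y]
    hessian = p0 * (1 - p0)

    best = None  # (sse, feature, threshold)
    n_feat = len(X[0])
    for j in range(n_feat):
        values = sorted(set(row[j] for row in X))
        for lo, hi in zip(values, values[1:]):
            thr = (lo + hi) / 2.0
            left = [residual[i] for i in range(n) if X[i][j] <= thr]
            right = [residual[i] for i in range(n) if X[i][j] > thr]
            sse = 0.0
            for group in (left, right):
                mu = sum(group) / len(group)
                sse += sum((r - mu) ** 2 for r in group)
            if best is None or sse < best[0] - 1e-12:
                best = (sse, j, thr)
    _, j, thr = best
    scores = []
    for i in range(n):
        leaf = [k for k in range(n) if (X[k][j] <= thr) == (X[i][j] <= thr)]
        value = sum(residual[k] for k in leaf) / (hessian * len(leaf))
        scores.append(f0 + learning_rate * value)
    return scores
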