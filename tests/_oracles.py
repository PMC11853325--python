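"""Independent brute-force oracles used by the tests (plain Python,
deliberately separate from the package's vectorized implementations)."""

import math
import statistics


def brute_force_features(x):
    """The 12 window statistics computed with loops and the statistics module."""
    x = [float(v) for v in x]
    n = len(x)
    mu = sum(x) / n
    var = sum((v - mu) ** 2 for v in x) / n
    sd = math.sqrt(var)
    ms = sum(v * v for v in x) / n
    rms = math.sqrt(ms)
    mean_abs = sum(abs(v) for v in x) / n
    med = statistics.median(x)
    return {
        "Min": min(x),
        "Max": max(x),
        "Mean": mu,
        "Std": sd,
        "RMS": rms,
        "Skewness": sum((v - mu) ** 3 for v in x) / n / sd**3 if sd > 0 else 0.0,
        "Kurtosis": sum((v - mu) ** 4 for v in x) / n / sd**4 if sd > 0 else 0.0,
        "Crest": max(abs(v) for v in x) / rms if rms > 0 else 0.0,
        "Shape": rms / mean_abs if rms > 0 else 0.0,
        "MeanAD": sum(abs(v - mu) for v in x) / n,
        "MedianAD": statistics.median(abs(v - med) for v in x),
        "L2": math.sqrt(sum(v * v for v in x)),
    }


def pair_count_auc(y, scores):
    """All-pairs Mann-Whitney AUC with ties counted one half."""
    pos = [s for s, label in zip(scores, y) if label == 1]
    neg = [s for s, label in zip(scores, y) if label == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))
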