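"""Independent brute-force reference implementations.

Plain Python loops over matrix entries, written directly from the definitions
of frequency, population statistics, replicate merging and the z-score. Kept
deliberately free of the package's vectorized code paths so tests can compare
the two routes.
"""

import math


def brute_frequency(raw_rows: list[list[float]], n_ips: int) -> list[float]:
    """f per protein: detections (raw > 0) / n_ips."""
    out = []
    for row in raw_rows:
        detections = 0
        for v in row:
            if v > 0:
                detections += 1
        out.append(detections / n_ips)
    return out


def brute_log10(raw_rows: list[list[float]]) -> list[list[float]]:
    """Zero -> 1 substitution then elementwise log10."""
    return [[math.log10(v if v > 0 else 1.0) for v in row] for row in raw_rows]


def brute_population_stats(
    log_rows: list[list[float]], ddof: int = 0
) -> tuple[list[float], list[float]]:
    """Per-protein mean and sd over all IPs (zeros included)."""
    mus, sds = [], []
    for row in log_rows:
        n = len(row)
        mu = sum(row) / n
        ss = sum((v - mu) ** 2 for v in row)
        sd = math.sqrt(ss / (n - ddof)) if n - ddof > 0 else float("nan")
        mus.append(mu)
        sds.append(sd)
    return mus, sds


def brute_merged(
    raw_rows: list[list[float]],
    log_rows: list[list[float]],
    replicate_cols: list[int],
) -> list[float]:
    """Merged intensity per protein over one antibody's replicate columns:
    mean of log values if detected (raw > 0) in every replicate, else NaN."""
    out = []
    for raw_row, log_row in zip(raw_rows, log_rows):
        if all(raw_row[j] > 0 for j in replicate_cols):
            out.append(sum(log_row[j] for j in replicate_cols) / len(replicate_cols))
        else:
            out.append(float("nan"))
    return out


def brute_z(merged: list[float], mus: list[float], sds: list[float]) -> list[float]:
    """z = (merged - mu) / sd; NaN when merged undefined or sd == 0."""
    out = []
    for m, mu, sd in zip(merged, mus, sds):
        if math.isnan(m) or sd == 0:
            out.append(float("nan"))
        else:
            out.append((m - mu) / sd)
    return out
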