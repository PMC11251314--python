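"""Independent brute-force oracle for the filter cascades.

Pure-Python, per-gene, straight from the inequality definitions on raw TPM
vectors — deliberately shares no code with the vectorised implementation it
cross-checks.
"""

import math


def log2_stats(values, ddof=1):
    logs = [math.log2(v) for v in values]
    n = len(logs)
    mean = sum(logs) / n
    var = sum((x - mean) ** 2 for x in logs) / (n - ddof)
    sd = math.sqrt(var)
    dev = max(abs(x - mean) for x in logs)
    return mean, sd, dev


def oracle_reference(genes, thresholds=None, ddof=1):
    """genes: mapping id -> TPM vector.  Returns list of (rank, id, sd,
    mean, cv) ordered CV-ascending with lexicographic tie-break."""
    thr = thresholds
    min_tpm = 0.0 if thr is None else thr.min_tpm
    sd_max = 1.0 if thr is None else thr.sd_max
    dev_max = 2.0 if thr is None else thr.dev_max
    mean_min = 5.0 if thr is None else thr.mean_min
    cv_max = 0.2 if thr is None else thr.cv_max
    kept = []
    for gid, vals in genes.items():
        if not all(v > min_tpm for v in vals):
            continue
        mean, sd, dev = log2_stats(vals, ddof)
        if not sd < sd_max:
            continue
        if not dev < dev_max:
            continue
        if not mean > mean_min:
            continue
        if not (mean > 0 and sd / mean < cv_max):
            continue
        kept.append((gid, sd, mean, sd / mean))
    kept.sort(key=lambda e: (e[3], e[0]))
    return [(i, g, sd, m, cv) for i, (g, sd, m, cv) in enumerate(kept, start=1)]


def oracle_validation(genes, thresholds=None, ddof=1):
    """Returns list of (rank, id, sd, mean) ordered SD-descending."""
    thr = thresholds
    min_tpm = 0.0 if thr is None else thr.min_tpm
    sd_min = 1.0 if thr is None else thr.sd_min
    mean_min = 5.0 if thr is None else thr.mean_min
    kept = []
    for gid, vals in genes.items():
        if not all(v > min_tpm for v in vals):
            continue
        mean, sd, _ = log2_stats(vals, ddof)
        if not sd > sd_min:
            continue
        if not mean > mean_min:
            continue
        kept.append((gid, sd, mean))
    kept.sort(key=lambda e: (-e[1], e[0]))
    return [(i, g, sd, m) for i, (g, sd, m) in enumerate(kept, start=1)]


def random_gene_pool(rng, n_genes, n_cond):
    """TPM vectors spanning every filter regime, including exact zeros."""
    genes = {}
    for i in range(n_genes):
        kind = rng.integers(0, 4)
        if kind == 0:  # near-constant, high
            base = rng.uniform(4.0, 9.5)
            logs = base + rng.normal(0, rng.uniform(0.01, 0.5), n_cond)
        elif kind == 1:  # noisy
            base = rng.uniform(-5.0, 9.5)
            logs = base + rng.normal(0, rng.uniform(0.8, 4.0), n_cond)
        elif kind == 2:  # stable low
            base = rng.uniform(0.2, 5.5)
            logs = base + rng.normal(0, rng.uniform(0.01, 0.3), n_cond)
        else:  # anything
            logs = rng.uniform(-6.0, 10.0, n_cond)
        vals = [float(2.0 ** x) for x in logs]
        if rng.random() < 0.15:  # sprinkle exact zeros
            vals[int(rng.integers(0, n_cond))] = 0.0
        genes[f"g{i:04d}"] = vals
    return genes
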