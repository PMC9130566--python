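"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's vectorized code paths: plain Python
loops and ``statistics``-style arithmetic, so they can serve as oracles for
the pipeline's window statistics, pi, D_XY and the shared-nonsynonymous
count.
"""

import math


def brute_force_window_stats(snps, window=20, step=10, offset=1):
    """Per-scaffold window means of per-SNP mean standardized |dAF|.

    Returns {scaffold: [(start_index_1based, span, stat), ...]} computed with
    explicit loops from the SnpTable's frequencies.
    """
    anad = [i for i, p in enumerate(snps.pools) if p.life_history == "anadromous"]
    fresh = [i for i, p in enumerate(snps.pools) if p.life_history == "freshwater"]
    freqs = snps.freqs
    S = snps.n_sites
    pairs = [(a, f) for a in anad for f in fresh]

    # genome-wide per-pair standardization with population sd
    z_per_site = [0.0] * S
    for (a, f) in pairs:
        d = [abs(freqs[i][f] - freqs[i][a]) for i in range(S)]
        mean = sum(d) / S
        var = sum((x - mean) ** 2 for x in d) / S
        sd = math.sqrt(var)
        for i in range(S):
            z_per_site[i] += (d[i] - mean) / sd
    mean_z = [z / len(pairs) for z in z_per_site]

    by_scaffold = {}
    for i in range(S):
        by_scaffold.setdefault(str(snps.scaffold[i]), []).append(i)
    out = {}
    for scaffold, idx in by_scaffold.items():
        rows = []
        start = offset - 1
        while start + window <= len(idx):
            sel = idx[start:start + window]
            stat = sum(mean_z[i] for i in sel) / window
            span = (int(snps.position[sel[0]]), int(snps.position[sel[-1]]))
            rows.append((start + 1, span, stat))
            start += step
        out[scaffold] = rows
    return out


def brute_force_window_pi(snps, pool_index, site_indices):
    """Mean per-site pool pi over the given sites, looped per site."""
    total, n = 0.0, 0
    for i in site_indices:
        minor = int(snps.minor_count[i][pool_index])
        major = int(snps.major_count[i][pool_index])
        c = minor + major
        if c < 2:
            continue
        p = minor / c
        total += c / (c - 1) * (1 - p * p - (1 - p) * (1 - p))
        n += 1
    return total / n


def brute_force_window_dxy(snps, site_indices):
    """Mean site D_XY over sites and all anadromous x freshwater pairs."""
    anad = [i for i, p in enumerate(snps.pools) if p.life_history == "anadromous"]
    fresh = [i for i, p in enumerate(snps.pools) if p.life_history == "freshwater"]
    freqs = snps.freqs
    total, n = 0.0, 0
    for i in site_indices:
        for a in anad:
            for f in fresh:
                p1, p2 = freqs[i][a], freqs[i][f]
                total += p1 * (1 - p2) + p2 * (1 - p1)
                n += 1
    return total / n


def brute_force_nearest_rank(values, percentile):
    ranked = sorted(values)
    k = math.ceil(percentile / 100 * len(ranked))
    return ranked[max(k, 1) - 1]


def brute_force_shared_nonsyn_count(sites_a, sites_b, percentile):
    """Exhaustive shared-nonsynonymous count.

    ``sites_a``/``sites_b``: {(scaffold, pos): z} over each lineage's
    nonsynonymous sites.
    """
    thr_a = brute_force_nearest_rank(list(sites_a.values()), percentile)
    thr_b = brute_force_nearest_rank(list(sites_b.values()), percentile)
    count = 0
    for key in sites_a:
        if key in sites_b and sites_a[key] >= thr_a and sites_b[key] >= thr_b:
            count += 1
    return count
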