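"""Shared builders for test fixtures."""

import numpy as np
import pandas as pd

from evmirna.containers import CountMatrix


def toy_count_matrix(counts, mirna_ids=None, sample_meta=None):
    """Build a CountMatrix from a 2-D array; defaults every sample to the
    iPSC day-0 IC cell so design invariants hold for format-level toys."""
    counts = np.asarray(counts)
    g, n = counts.shape
    if mirna_ids is None:
        mirna_ids = [f"mir-{i}" for i in range(g)]
    sample_ids = [f"s{j}" for j in range(n)]
    if sample_meta is None:
        sample_meta = pd.DataFrame(
            {
                "genotype": ["IC"] * n,
                "region": ["iPSC"] * n,
                "timepoint": ["D0"] * n,
                "replicate": list(range(1, n + 1)),
            },
            index=sample_ids,
        )
    return CountMatrix(
        pd.DataFrame(counts, index=mirna_ids, columns=sample_ids), sample_meta
    )


def ic_sample_sheet(replicates=3):
    """Sample sheet covering all 7 IC condition cells."""
    rows = []
    for r, t in [("iPSC", "D0")] + [
        (r, t) for r in ("dorsal", "ventral") for t in ("D13", "D40", "D75")
    ]:
        for k in range(1, replicates + 1):
            rows.append((f"IC_{r}_{t}_r{k}", "IC", r, t, k))
    df = pd.DataFrame(
        rows, columns=["sample_id", "genotype", "region", "timepoint", "replicate"]
    )
    return df.set_index("sample_id")


def two_group_design(n_per_group=3):
    """Minimal 2-coefficient one-hot design over 2*n samples."""
    n = 2 * n_per_group
    sample_ids = [f"s{j}" for j in range(n)]
    X = pd.DataFrame(0.0, index=sample_ids, columns=["A", "B"])
    X.iloc[:n_per_group, 0] = 1.0
    X.iloc[n_per_group:, 1] = 1.0
    return X


def oracle_tmm_pair(obs, ref, trim_m=0.30, trim_a=0.05):
    """Independent straight-line TMM factor: explicit loops, sorting-based
    double trim, precision-weighted mean. Shares no code with the package."""
    obs, ref = np.asarray(obs, float), np.asarray(ref, float)
    lo, lr = obs.sum(), ref.sum()
    m, a, w = [], [], []
    for o, r in zip(obs, ref):
        if o > 0 and r > 0:
            po, pr = o / lo, r / lr
            m.append(np.log2(po / pr))
            a.append(0.5 * np.log2(po * pr))
            w.append((lo - o) / (lo * o) + (lr - r) / (lr * r))
    m, a, w = np.array(m), np.array(a), np.array(w)
    n = len(m)
    keep = np.ones(n, bool)
    for vals, trim in ((m, trim_m), (a, trim_a)):
        lo_k = int(np.floor(n * trim)) + 1
        hi_k = n + 1 - lo_k
        ranks = vals.argsort().argsort() + 1  # no ties in fixtures
        keep &= (ranks >= lo_k) & (ranks <= hi_k)
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return 2.0**f


def hypergeom_tail_oracle(k, N, K, n):
    """P(X >= k) by direct pmf enumeration."""
    from math import comb

    return sum(
        comb(K, j) * comb(N - K, n - j) / comb(N, n) for j in range(k, min(K, n) + 1)
    )
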