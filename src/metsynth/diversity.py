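"""Alpha diversity (Shannon, Pielou, observed features) and the Mantel test.

Shannon entropy uses natural log over nonzero proportions; Pielou's evenness
is H / ln(observed features) and is reported as 0 (with a warning) for
single-feature samples rather than NaN so degenerate synthetic samples do
not break pipelines. Phylogeny-dependent metrics (Faith's PD, UniFrac) are
out of scope; the Mantel test operates on supplied distance matrices.
"""

from __future__ import annotations

import warnings
from itertools import permutations

import numpy as np
import pandas as pd

from metsynth.exceptions import DegenerateDataError, SchemaError


def alpha_diversity(counts) -> pd.DataFrame:
    """Per-sample Shannon H, Pielou J and observed-feature richness.

    ``counts`` is a feature x sample table (DataFrame) or a single vector.
    """
    df = pd.DataFrame(counts)
    rows = []
    for sample in df.columns:
        v = df[sample].to_numpy(dtype=float)
        if (v < 0).any():
            raise SchemaError("negative counts")
        total = v.sum()
        if total == 0:
            raise DegenerateDataError(f"all-zero sample {sample}")
        p = v[v > 0] / total
        h = float(-(p * np.log(p)).sum())
        observed = int((v > 0).sum())
        if observed == 1:
            warnings.warn(f"sample {sample} has one feature; Pielou set to 0")
            j = 0.0
        else:
            j = h / np.log(observed)
        rows.append({"sample": sample, "shannon": h, "pielou": j,
                     "observed": observed})
    return pd.DataFrame(rows).set_index("sample")


def _validate_distance(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise SchemaError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10) or not np.allclose(np.diag(d), 0.0):
        raise SchemaError("distance matrix must be symmetric with zero diagonal")
    if (d < 0).any():
        raise SchemaError("distances must be non-negative")
    return d


def mantel_test(d1, d2, n_permutations: int = 999, seed: int = 0,
                exact: bool = False) -> tuple[float, float]:
    """Mantel test: Pearson correlation of upper-triangle distances with a
    permutation p by simultaneous row/column shuffling of one matrix.

    Two-sided p = (1 + #{|r_perm| >= |r_obs|}) / (B + 1); ``exact=True``
    enumerates all n! permutations instead (tiny n only).
    """
    a = _validate_distance(getattr(d1, "values", d1))
    b = _validate_distance(getattr(d2, "values", d2))
    if a.shape != b.shape:
        raise SchemaError("distance matrices differ in size")
    n = a.shape[0]
    if n < 4:
        raise DegenerateDataError("need >= 4 samples")
    iu = np.triu_indices(n, k=1)

    def corr(mat: np.ndarray) -> float:
        return float(np.corrcoef(a[iu], mat[iu])[0, 1])

    r_obs = corr(b)
    if exact:
        perms = [np.array(p) for p in permutations(range(n))]
        count = sum(abs(corr(b[np.ix_(p, p)])) >= abs(r_obs) - 1e-12 for p in perms)
        return r_obs, count / len(perms)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        p = rng.permutation(n)
        if abs(corr(b[np.ix_(p, p)])) >= abs(r_obs) - 1e-12:
            count += 1
    return r_obs, (1 + count) / (n_permutations + 1)
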