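"""Brute-force oracles shared by the acceptance checks.

These deliberately avoid the package's own shortcuts: the rank-sum oracle
enumerates all pairs, and the RDA oracle rebuilds the constrained axes from a
dense eigendecomposition of the fitted cross-product.
"""

import numpy as np
import pandas as pd

from clinescan.parallelism import rank_sum_z
from clinescan.rda import fit_rda


def check_rank_sum_instances(n_instances=500, seed=0):
    rng = np.random.default_rng(seed)
    for _ in range(n_instances):
        n1, n2 = rng.integers(1, 51, size=2)
        c = rng.integers(0, 10, size=n1) / 5.0
        g = rng.integers(0, 10, size=n2) / 5.0
        w, z = rank_sum_z(g, c)
        w_ref = 0.0
        for gi in g:
            for ci in c:
                if gi > ci:
                    w_ref += 1.0
                elif gi == ci:
                    w_ref += 0.5
        z_ref = (2 * w_ref - n1 * n2) / np.sqrt(n1 * n2 * (n1 + n2 + 1) / 3)
        assert w == w_ref
        assert abs(z - z_ref) < 1e-12


def check_rda_toys(n_toys=20, seed=0):
    from conftest import make_variant_table

    rng = np.random.default_rng(seed)
    for _ in range(n_toys):
        n = int(rng.integers(8, 25))
        m = int(rng.integers(3, 12))
        p = int(rng.integers(1, min(4, n - 2)))
        y = rng.normal(size=(n, m))
        x = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"v{j}" for j in range(p)])
        model = fit_rda(make_variant_table(y), x)
        xs = (x - x.mean()) / x.std(ddof=1)
        xs = xs.to_numpy()
        yc = y - y.mean(axis=0)
        fitted = xs @ np.linalg.lstsq(xs, yc, rcond=None)[0]
        evals, evecs = np.linalg.eigh(fitted.T @ fitted / (n - 1))
        order = np.argsort(evals)[::-1][: model.n_axes]
        np.testing.assert_allclose(model.eigenvalues, evals[order], atol=1e-8)
        for a in range(model.n_axes):
            ref, got = evecs[:, order[a]], model.locus_scores[:, a]
            assert min(np.abs(got - ref).max(), np.abs(got + ref).max()) < 1e-8
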