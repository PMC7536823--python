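"""Shared fixtures: small planted datasets and independent brute-force
oracles for the recovery-curve AUC, the CSI transform and the Gini
coefficient.  The oracles deliberately use naive enumeration so they stay
independent of the vectorised implementations they check."""

import numpy as np
import pandas as pd
import pytest

import regulonatlas as ra


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def aucell_oracle(ranks: dict, gene_set: set, top_fraction: float) -> float:
    """Explicit recovery-curve enumeration: walk the ranking position by
    position, count recovered set genes at each step, normalise by the best
    achievable curve."""
    n = len(ranks)
    T = int(np.floor(top_fraction * n))
    raw = 0
    for k in range(1, T + 1):
        raw += sum(1 for g in gene_set if ranks[g] <= k)
    best = 0
    m = len(gene_set)
    for k in range(1, T + 1):
        best += min(k, m)
    return raw / best


def csi_oracle(P: np.ndarray, delta: float) -> np.ndarray:
    """Double-loop enumeration of the printed CSI formula."""
    n = P.shape[0]
    out = np.ones((n, n))
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            thr = P[a, b] - delta
            count = 0
            for c in range(n):
                if P[c, a] >= thr or P[c, b] >= thr:
                    count += 1
            out[a, b] = 1.0 - count / n
    return out


def gini_oracle(x) -> float:
    """Half relative mean absolute difference, O(n^2)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    mad = sum(abs(xi - xj) for xi in x for xj in x) / (n * n)
    return mad / (2 * x.mean())


# ---------------------------------------------------------------------------
# small planted datasets
# ---------------------------------------------------------------------------


SMALL_SCALE = dict(
    n_tfs=10, n_targets=8, n_modules=3, n_cell_types=6, n_groups=3, n_genes=200
)


@pytest.fixture(scope="session")
def small_truth():
    return ra.generate_ground_truth(seed=7, **SMALL_SCALE)


@pytest.fixture(scope="session")
def small_profile():
    return ra.AtlasProfile("mini", 2000.0, 0.0, 1.0, "reference", 300)


@pytest.fixture(scope="session")
def small_atlas(small_truth, small_profile):
    return ra.generate_atlas(small_truth, small_profile, seed=3)


@pytest.fixture()
def tiny_expr():
    rng = np.random.default_rng(0)
    values = rng.poisson(3.0, size=(20, 15))
    genes = ["g%02d" % i for i in range(20)]
    cells = ["c%02d" % i for i in range(15)]
    return ra.ExpressionMatrix(values, genes, cells)


# ---------------------------------------------------------------------------
# the full default-scale study run (shared by the acceptance tests)
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Full pipeline at the default synthetic scale (3 atlases x 3,000 cells
    x 1,500 genes, 25 TFs, 5 modules, noiseless motif db), seed 1."""
    from regulonatlas.pipeline import load_config, run_pipeline

    outdir = tmp_path_factory.mktemp("default_run")
    cfg = load_config(overrides={"outdir": str(outdir), "seed": 1})
    run_pipeline(cfg)
    return outdir


@pytest.fixture(scope="session")
def low_noise_harmonisation(tmp_path_factory):
    """Synthesis + harmonisation only, in low-noise mode, seed 1."""
    from regulonatlas.io_formats import read_json
    from regulonatlas.pipeline import load_config, run_stage

    outdir = tmp_path_factory.mktemp("low_noise")
    cfg = load_config(
        overrides={"outdir": str(outdir), "seed": 1, "synth": {"low_noise": True}}
    )
    run_stage("synth", cfg)
    run_stage("harmonise", cfg)
    return read_json(outdir / "harmonise_summary.json")
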