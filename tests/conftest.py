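import numpy as np
import pytest

from ventgrowth.design import generate_design
from ventgrowth.richards import RichardsParams
from ventgrowth.simulate import GroundTruth, simulate_wells


@pytest.fixture
def small_design():
    """A 2×2×2 factorial, 2 replicates, 12 daily readings, with controls."""
    return generate_design(
        salinities=[0.0, 30.0],
        phs=[3.0, 7.0],
        temperatures=[15.0, 25.0],
        replicates=2,
        organisms=["org_a"],
        days=12,
    )


@pytest.fixture
def small_truth(small_design):
    """Noiseless truth: growth everywhere except pH 3 at 25 °C."""
    params = RichardsParams(a=0.8, k=0.6, d=2.0, xc=5.0)
    cells = {}
    for s, p, t in small_design.treatments:
        grows = not (p == 3.0 and t == 25.0)
        cells[("org_a", s, p, t)] = params if grows else None
    return GroundTruth(cells=cells, noise_sd=0.0, baseline=0.05, seed=7)


@pytest.fixture
def small_wells(small_design, small_truth):
    return simulate_wells(small_design, small_truth)


def brute_force_kruskal(groups):
    """Tie-corrected Kruskal-Wallis H computed directly from the rank
    definition: H = [12/(N(N+1))] Σ n_i (R̄_i − (N+1)/2)², divided by
    C = 1 − Σ(t³−t)/(N³−N)."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    n_total = len(pooled)
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(n_total)
    i = 0
    sorted_vals = pooled[order]
    while i < n_total:
        j = i
        while j < n_total and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + 1 + j) / 2.0  # average rank of tie block
        i = j
    h = 0.0
    start = 0
    for g in groups:
        n_i = len(g)
        mean_rank = ranks[start:start + n_i].mean()
        h += n_i * (mean_rank - (n_total + 1) / 2.0) ** 2
        start += n_i
    h *= 12.0 / (n_total * (n_total + 1))
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n_total**3 - n_total)
    return h / correction if correction > 0 else 0.0


def brute_force_dunn_z(groups):
    """Pairwise Dunn z statistics from first principles (mean ranks and
    the tie-corrected pooled variance), keyed by group-index pair."""
    import itertools
    from scipy.stats import rankdata

    arrays = [np.asarray(g, float) for g in groups]
    pooled = np.concatenate(arrays)
    n = len(pooled)
    ranks = rankdata(pooled)
    mean_ranks, sizes, start = [], [], 0
    for g in arrays:
        mean_ranks.append(ranks[start:start + len(g)].mean())
        sizes.append(len(g))
        start += len(g)
    _, counts = np.unique(pooled, return_counts=True)
    ties = np.sum(counts**3 - counts)
    core = n * (n + 1) / 12.0 - ties / (12.0 * (n - 1))
    out = {}
    for i, j in itertools.combinations(range(len(arrays)), 2):
        se = np.sqrt(core * (1 / sizes[i] + 1 / sizes[j]))
        out[(i, j)] = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
    return out
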