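import numpy as np
import pandas as pd
import pytest

from brainsig import synthetic
from brainsig.volumes import BinaryMask, CohortTable, Volume, make_analysis_mask


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_cohort_table(n, seed=0, outcome_name="memory", diagnosis=True):
    """A plain cohort table with random demographics and outcome."""
    r = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "subject_id": [f"s{i:03d}" for i in range(n)],
            "age": r.uniform(55, 90, n),
            "gender": r.integers(0, 2, n).astype(float),
            "education": r.uniform(8, 20, n),
            outcome_name: r.standard_normal(n),
        }
    )
    if diagnosis:
        df["diagnosis"] = r.choice(["CN", "MCI", "Dementia"], n)
    return CohortTable(df, outcomes=(outcome_name,))


@pytest.fixture(scope="session")
def small_sim():
    """A 16^3 cohort of 60 subjects with one planted box effect."""
    cfg = synthetic.GenerativeConfig(
        n_subjects=60,
        shape=(16, 16, 16),
        effects=(synthetic.EffectSpec("box", (8, 8, 8), 3, 0.09),),
        seed=42,
    )
    return synthetic.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_mask(small_sim):
    return make_analysis_mask(small_sim.template, 0.5)


def random_mask(shape, p, seed):
    r = np.random.default_rng(seed)
    return BinaryMask(r.random(shape) < p)


def bfs_components(mask_data, connectivity):
    """Independent flood-fill connected components (oracle)."""
    from collections import deque

    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                manh = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and manh > 1:
                    continue
                if connectivity == 18 and manh > 2:
                    continue
                offsets.append((dx, dy, dz))
    shape = mask_data.shape
    visited = np.zeros(shape, dtype=bool)
    comps = []
    for start in zip(*np.nonzero(mask_data)):
        if visited[start]:
            continue
        comp = []
        q = deque([start])
        visited[start] = True
        while q:
            pt = q.popleft()
            comp.append(np.ravel_multi_index(pt, shape))
            for off in offsets:
                nb = tuple(p + o for p, o in zip(pt, off))
                if all(0 <= c < s for c, s in zip(nb, shape)):
                    if mask_data[nb] and not visited[nb]:
                        visited[nb] = True
                        q.append(nb)
        comps.append(np.sort(np.array(comp)))
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps
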