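import numpy as np
import pytest

from dockselect.data import PerformanceTable, Portfolio, SolverConfig
from dockselect.scoring import ScoringConfig, rmsd_score
from dockselect.synthetic import generate, planted_spec


def make_table_from_scores(scores) -> PerformanceTable:
    """Table with prescribed composite scores (success matrices all-zero)."""
    scores = np.asarray(scores, dtype=float)
    n, m = scores.shape
    portfolio = Portfolio([SolverConfig(f"s{j}", f"s{j}") for j in range(m)])
    zeros = np.zeros((n, m), dtype=int)
    return PerformanceTable(
        instance_ids=[f"i{i}" for i in range(n)],
        portfolio=portfolio,
        rmsd=np.zeros((n, m)),
        pb_valid=np.ones((n, m), dtype=int),
        scores=scores,
        success_strict=zeros,
        success_relaxed=zeros.copy(),
        missing_mask=np.zeros((n, m), dtype=bool),
    )


def make_random_table(rng: np.random.Generator, n: int, m: int) -> PerformanceTable:
    """Random but internally consistent table derived from rmsd/pb draws."""
    scoring = ScoringConfig()
    rmsd = rng.uniform(0.0, 6.0, size=(n, m))
    pb = (rng.random((n, m)) < 0.8).astype(int)
    portfolio = Portfolio([SolverConfig(f"s{j}", f"s{j}") for j in range(m)])
    return PerformanceTable(
        instance_ids=[f"i{i}" for i in range(n)],
        portfolio=portfolio,
        rmsd=rmsd,
        pb_valid=pb,
        scores=rmsd_score(rmsd, scoring) * pb,
        success_strict=((rmsd <= 1.0) & (pb == 1)).astype(int),
        success_relaxed=((rmsd <= 2.0) & (pb == 1)).astype(int),
        missing_mask=np.zeros((n, m), dtype=bool),
        scoring=scoring,
    )


@pytest.fixture(scope="session")
def small_bench():
    """Planted 3-regime benchmark, small enough for fast training tests."""
    return generate(planted_spec(n_instances=240, m_solvers=6, n_regimes=3,
                                 separability=6.0, seed=0))
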