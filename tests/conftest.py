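import numpy as np
import pytest

from medipdmr.core import CpGMap, DepthMatrix, StudyDesign
from medipdmr.simulate import SimulationParams, simulate_cpg_map, simulate_depth_matrix


@pytest.fixture(scope="session")
def design10() -> StudyDesign:
    return StudyDesign.paired(10)


@pytest.fixture(scope="session")
def design3() -> StudyDesign:
    return StudyDesign.paired(3)


@pytest.fixture(scope="session")
def small_sim_params() -> SimulationParams:
    """A fast simulation: 1,000 CpGs on one chromosome, 5 planted windows."""
    return SimulationParams(n_chroms=1, n_cpgs=1000, n_planted_dmrs=5, seed=11)


@pytest.fixture(scope="session")
def small_study(small_sim_params, design10):
    cpg_map = simulate_cpg_map(small_sim_params)
    matrix, truth = simulate_depth_matrix(cpg_map, design10, small_sim_params)
    return matrix, truth


def make_matrix(depths: np.ndarray, positions, design: StudyDesign, chrom="chr1") -> DepthMatrix:
    """Hand-built single-chromosome depth matrix for targeted tests."""
    pos = np.asarray(positions, dtype=np.int64)
    cpg_map = CpGMap({chrom: pos}, {chrom: int(pos[-1]) + 1000})
    return DepthMatrix(cpg_map, np.asarray(depths), design)
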