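import numpy as np
import pytest

from octaquant import SyntheticSpec, generate_tree
from octaquant.vessel_map import DEFAULT_PITCH_MM


@pytest.fixture(scope="session")
def pitch() -> float:
    return DEFAULT_PITCH_MM


@pytest.fixture(scope="session")
def clean_tree():
    """One noise-free 512x512 retinal synthetic image with ground truth."""
    return generate_tree(SyntheticSpec(target_perfusion=0.30, noise=0.0, seed=7))


@pytest.fixture(scope="session")
def noisy_tree():
    """Same network with 0.1 multiplicative speckle."""
    return generate_tree(SyntheticSpec(target_perfusion=0.30, noise=0.1, seed=7))


def brute_force_perfusion(mask: np.ndarray, region: np.ndarray) -> float:
    """Independent double-loop pixel counter (oracle for density metrics)."""
    num = den = 0
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            if region[i, j]:
                den += 1
                if mask[i, j]:
                    num += 1
    return num / den


def brute_force_skeleton_density(skel: np.ndarray, region: np.ndarray, pitch_mm: float) -> float:
    """Independent length-per-area computation: count pixels in two loops."""
    count = den = 0
    for i in range(skel.shape[0]):
        for j in range(skel.shape[1]):
            if region[i, j]:
                den += 1
                if skel[i, j]:
                    count += 1
    return (count * pitch_mm) / (den * pitch_mm**2)
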