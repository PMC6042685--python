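"""Shared fixtures and independent oracle helpers."""

from __future__ import annotations

import math

import numpy as np
import pytest

from nociquant import LATENCY_CAP_S


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    a, b = np.asarray(a, bool), np.asarray(b, bool)
    union = np.logical_or(a, b).sum()
    return np.logical_and(a, b).sum() / union if union else 1.0


def reconstruct_latency_sample(
    n: int, mean: float, se: float, cap: float = LATENCY_CAP_S
) -> np.ndarray:
    """Deterministic synthetic latency sample with exactly the given
    n / mean / SE (sample sd, ddof=1), values in (0, cap].

    Places k animals at the censoring cap and splits the rest into pairs
    ``m' ± d`` around the residual mean; k is the smallest count for which
    the residual variance is achievable within (0, cap].
    """
    target_ss = (se * math.sqrt(n)) ** 2 * (n - 1)  # sum of (x - mean)^2
    for k in range(n):
        n_rest = n - k
        m_rest = (n * mean - cap * k) / n_rest
        if not 0 < m_rest <= cap:
            continue
        ss_rest = target_ss - k * (cap - mean) ** 2 - n_rest * (m_rest - mean) ** 2
        if ss_rest < -1e-9:
            continue
        n_pairs = n_rest // 2
        vals = [cap] * k
        if n_rest % 2:
            vals.append(m_rest)
        d = math.sqrt(max(ss_rest, 0.0) / (2 * n_pairs)) if n_pairs else 0.0
        if not (0 < m_rest - d and m_rest + d <= cap):
            continue
        vals.extend([m_rest - d] * n_pairs)
        vals.extend([m_rest + d] * n_pairs)
        out = np.array(vals)
        assert abs(out.mean() - mean) < 1e-9
        return out
    raise ValueError("no feasible reconstruction for these moments")


@pytest.fixture(scope="session")
def soma_default_truth():
    from nociquant import make_soma_truth

    return make_soma_truth()


@pytest.fixture(scope="session")
def clone_default():
    from nociquant import generate_clone_image, make_clone_truth

    truth = make_clone_truth()
    stack, truth = generate_clone_image(truth, seed=11)
    return stack, truth
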