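"""Shared fixtures and independent oracle helpers.

The oracles here deliberately re-derive quantities by brute force or
closed form, independent of the library's code paths, so tests compare
two routes to the same number.
"""

from __future__ import annotations

import numpy as np
import pytest

import lrrwind as lw


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_solenoid():
    """One mid-size clean solenoid with flanks, shared across tests."""
    spec = lw.SolenoidSpec(
        n_pre=150, period=25.0, n_turns=20.0, n_post=150, noise_sd=0.3, seed=1
    )
    trace, truth = lw.generate(spec)
    return trace, truth


@pytest.fixture(scope="session")
def bare_helix():
    """Flankless, noise-free helix: 8 turns of period 25, radius 3."""
    spec = lw.SolenoidSpec(
        n_pre=0, period=25.0, n_turns=8.0, radius=3.0, n_post=0, noise_sd=0.0, seed=0
    )
    trace, truth = lw.generate(spec)
    return trace, truth


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def unwrapped_angle_winding(points: np.ndarray) -> np.ndarray:
    """Oracle: cumulative winding as the unwrapped polar angle / 2π."""
    theta = np.unwrap(np.arctan2(points[:, 1], points[:, 0]))
    return (theta - theta[0]) / (2.0 * np.pi)


def direct_regression_loss(w, breakpoints, slope, c_weight=1.0, d_weight=1.5):
    """Oracle: literal per-segment summation of the piecewise loss."""
    w = np.asarray(w, dtype=float)
    t = np.arange(len(w), dtype=float)
    total = 0.0
    bps = list(breakpoints)
    for i in range(len(bps) - 1):
        a, b = bps[i], bps[i + 1]
        if b - a <= 1:
            continue
        if i % 2 == 0:
            seg = w[a:b]
            total += c_weight * float(np.sum((seg - seg.mean()) ** 2))
        else:
            seg = (w - slope * t)[a:b]
            total += d_weight * float(np.sum((seg - seg.mean()) ** 2))
    return total


def exhaustive_two_breakpoints(w, slope, c_weight=1.0, d_weight=1.5):
    """Oracle: full stride-1 enumeration of (a1, a2) minimizing the loss.

    Vectorized with its own prefix-sum algebra (independent of the
    library's evaluator).
    """
    w = np.asarray(w, dtype=float)
    n = len(w)
    t = np.arange(n, dtype=float)
    flat = w - w.mean()
    resid = w - slope * t
    resid = resid - resid.mean()

    def prefix(f):
        return (
            np.concatenate([[0.0], np.cumsum(f)]),
            np.concatenate([[0.0], np.cumsum(f * f)]),
        )

    f1, f2 = prefix(flat)
    r1, r2 = prefix(resid)

    def seg_var(s1, s2, a, b):
        length = b - a
        u = s1[b] - s1[a]
        u2 = s2[b] - s2[a]
        return np.where(length > 1, np.maximum(u2 - u * u / np.maximum(length, 1), 0.0), 0.0)

    a1 = np.arange(1, n - 1)
    a2 = np.arange(1, n)
    g1, g2 = np.meshgrid(a1, a2, indexing="ij")
    loss = (
        c_weight * seg_var(f1, f2, 0, g1)
        + d_weight * seg_var(r1, r2, g1, g2)
        + c_weight * seg_var(f1, f2, g2, n)
    )
    loss[g2 <= g1] = np.inf
    i, j = np.unravel_index(np.argmin(loss), loss.shape)
    return int(a1[i]), int(a2[j]), float(loss[i, j])


def brute_force_crossings(values, a, b, offset):
    """Oracle: scan every step for an integer straddle."""
    out = []
    for t in range(a + 1, b):
        lo, hi = values[t - 1] - offset, values[t] - offset
        if hi >= np.floor(lo) + 1 or hi <= np.ceil(lo) - 1:
            out.append(t)
    return out


def piecewise_profile(n_flat1, n_slope, n_flat2, slope, noise_sd=0.0, seed=0):
    """Flat / slope / flat winding profile with optional Gaussian noise."""
    rng = np.random.default_rng(seed)
    n = n_flat1 + n_slope + n_flat2
    w = np.empty(n)
    w[:n_flat1] = 0.0
    w[n_flat1 : n_flat1 + n_slope] = slope * np.arange(n_slope)
    w[n_flat1 + n_slope :] = slope * (n_slope - 1)
    if noise_sd > 0:
        w = w + rng.normal(0.0, noise_sd, n)
    return w
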