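import numpy as np
import pytest

from cgphase.fixtures import FixtureSpec, generate_fixture


@pytest.fixture(scope="session")
def toy_idp():
    return generate_fixture(FixtureSpec("toy_idp", seed=11))


@pytest.fixture(scope="session")
def harmonic_dimer():
    return generate_fixture(FixtureSpec("harmonic_dimer", seed=12))


@pytest.fixture(scope="session")
def dsdna_small():
    return generate_fixture(FixtureSpec("dsdna", seed=13))


def finite_difference_forces(force_fn, positions, h=1e-5):
    """Central-difference gradient of the scalar energy, -dE/dx."""
    fd = np.zeros_like(positions)
    for i in range(positions.shape[0]):
        for d in range(3):
            p = positions.copy()
            p[i, d] += h
            ep, _ = force_fn(p)
            p[i, d] -= 2 * h
            em, _ = force_fn(p)
            fd[i, d] = -(ep - em) / (2 * h)
    return fd


def assert_forces_match(force_fn, positions, rtol=1e-6, h=1e-5):
    e, f = force_fn(positions)
    fd = finite_difference_forces(force_fn, positions, h=h)
    scale = max(np.abs(f).max(), 1.0)
    assert np.abs(f - fd).max() <= rtol * scale, (
        f"max force deviation {np.abs(f - fd).max():.3e} vs scale {scale:.3e}")


def union_find_components(n, edges):
    """Independent connected-components oracle (no graph library)."""
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), set()).add(i)
    return sorted(comps.values(), key=lambda c: (-len(c), min(c)))
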